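"""Domain-pair scoring (ASSOC/ASNM/APM) and the noisy-OR strength combiner.

The reference implementations below are deliberately naive: direct loops
over the set-comprehension definitions of the scores and of the combined
probability, against which the package implementations are compared.
"""

import math
import random

import pytest

from ppistrength.association import (
    DDIScoreTable,
    apm_scores,
    asnm_scores,
    assoc_scores,
    coverage_filter,
    domain_pair_key,
    enumerate_domain_pairs,
    predict_strength,
)
from ppistrength.data_model import PairRecord

from conftest import make_dataset, random_dataset


# -- independent reference implementations ----------------------------------

def brute_force_tables(dataset):
    """ASNM and APM scores by direct enumeration of their definitions."""
    support = {}
    for pr in dataset.pairs:
        da = {d.domain_id for d in dataset.proteins[pr.protein_a].domains}
        db = {d.domain_id for d in dataset.proteins[pr.protein_b].domains}
        keys = {domain_pair_key(m, n) for m in da for n in db}
        for key in keys:  # a protein pair supports a domain pair once
            support.setdefault(key, []).append(pr)
    asnm, apm = {}, {}
    for key, prs in support.items():
        asnm[key] = sum(p.strength for p in prs) / len(prs)
        total = 0.0
        for p in prs:
            ci = len(dataset.proteins[p.protein_a].domains)
            cj = len(dataset.proteins[p.protein_b].domains)
            total += 1.0 - (1.0 - p.strength) ** (1.0 / (ci * cj))
        apm[key] = total / len(prs)
    return asnm, apm


def brute_force_combine(pair, scores, proteins):
    """1 - prod(1 - score) over domain instance pairs, by plain loops."""
    prod = 1.0
    for di in proteins[pair.protein_a].domains:
        for dj in proteins[pair.protein_b].domains:
            prod *= 1.0 - scores[domain_pair_key(di.domain_id, dj.domain_id)]
    return 1.0 - prod


# -- enumerate_domain_pairs --------------------------------------------------

def test_enumeration_matches_the_two_protein_worked_example():
    # P1 = {D1, D2}, P2 = {D2, D3, D4} yields exactly six unordered pairs
    ds = make_dataset(
        {"p1": ["D1", "D2"], "p2": ["D2", "D3", "D4"]}, {("p1", "p2"): 1.0}
    )
    got = enumerate_domain_pairs(ds.pairs[0], ds.proteins)
    assert got == {
        ("D1", "D2"), ("D1", "D3"), ("D1", "D4"),
        ("D2", "D2"), ("D2", "D3"), ("D2", "D4"),
    }


def test_enumeration_edge_cases():
    ds = make_dataset({"p1": [], "p2": ["D1"], "p3": ["D1"]},
                      {("p1", "p2"): 0.5, ("p2", "p3"): 0.5})
    assert enumerate_domain_pairs(ds.pairs[0], ds.proteins) == set()
    assert enumerate_domain_pairs(ds.pairs[1], ds.proteins) == {("D1", "D1")}


# -- ASSOC -------------------------------------------------------------------

def test_assoc_ratio_on_a_hand_built_instance():
    # (D1, D2) is supported by three pairs of which two interact -> 2/3
    ds = make_dataset(
        {"p1": ["D1"], "p2": ["D2"], "p3": ["D1"], "p4": ["D2"]},
        {("p1", "p2"): 1.0, ("p1", "p4"): 1.0, ("p2", "p3"): 0.0},
    )
    table = assoc_scores(ds)
    assert table[("D1", "D2")] == pytest.approx(2 / 3)
    assert table.counts[("D1", "D2")] == 3
    assert ("D1", "D1") not in table  # no supporting pair -> absent, not zero


def test_assoc_rejects_non_binary_strengths(toy_dataset):
    with pytest.raises(ValueError, match="binary"):
        assoc_scores(toy_dataset)


# -- ASNM / APM --------------------------------------------------------------

def test_asnm_is_the_mean_supporting_strength():
    ds = make_dataset(
        {"p1": ["D1"], "p2": ["D2"], "p3": ["D1"], "p4": ["D2"]},
        {("p1", "p2"): 0.2, ("p3", "p4"): 0.4},
    )
    assert asnm_scores(ds)[("D1", "D2")] == pytest.approx(0.3)


def test_asnm_equals_assoc_on_binary_strengths():
    rng = random.Random(11)
    for _ in range(20):
        ds = random_dataset(rng, binary=True)
        a, b = assoc_scores(ds), asnm_scores(ds)
        assert a.scores == b.scores and a.counts == b.counts


def test_apm_exponent_correction():
    # one supporting pair with |Pi| = |Pj| = 2 and rho = 0.75
    ds = make_dataset({"p1": ["D1", "D2"], "p2": ["D3", "D4"]}, {("p1", "p2"): 0.75})
    expected = 1.0 - 0.25 ** 0.25
    for key in [("D1", "D3"), ("D2", "D4")]:
        assert apm_scores(ds)[key] == pytest.approx(expected, abs=1e-12)
    # exponent 1 reduces APM to the raw strength
    single = make_dataset({"p1": ["D1"], "p2": ["D2"]}, {("p1", "p2"): 0.5})
    assert apm_scores(single)[("D1", "D2")] == pytest.approx(0.5)


def test_apm_requires_domains_on_both_proteins():
    ds = make_dataset({"p1": [], "p2": ["D1"]}, {("p1", "p2"): 0.5})
    with pytest.raises(ValueError, match="exponent"):
        apm_scores(ds)


def test_scores_match_brute_force_oracle_on_random_instances():
    rng = random.Random(23)
    for _ in range(25):
        ds = random_dataset(rng, n_proteins=10, n_pairs=14)
        ref_asnm, ref_apm = brute_force_tables(ds)
        asnm, apm = asnm_scores(ds), apm_scores(ds)
        assert set(asnm.keys()) == set(ref_asnm)
        assert set(apm.keys()) == set(ref_apm)  # same support sets
        for key in ref_asnm:
            assert asnm[key] == pytest.approx(ref_asnm[key], abs=1e-9)
            assert apm[key] == pytest.approx(ref_apm[key], abs=1e-9)
            # exponent correction can only shrink a supporting contribution
            assert apm[key] <= asnm[key] + 1e-12


# -- the combiner ------------------------------------------------------------

def _table(scores):
    return DDIScoreTable(dict(scores), "ASNM", {k: 1 for k in scores})


def test_combiner_product_and_absorbing_cases():
    ds = make_dataset({"p1": ["D1", "D2"], "p2": ["D3"]}, {("p1", "p2"): 0.5})
    pair = ds.pairs[0]
    t = _table({("D1", "D3"): 0.5, ("D2", "D3"): 0.5})
    assert predict_strength(pair, t, ds.proteins) == pytest.approx(0.75)
    assert predict_strength(pair, _table({("D1", "D3"): 0.0, ("D2", "D3"): 0.0}),
                            ds.proteins) == 0.0
    assert predict_strength(pair, _table({("D1", "D3"): 1.0, ("D2", "D3"): 0.3}),
                            ds.proteins) == 1.0


def test_combiner_counts_repeated_instances_twice():
    ds = make_dataset({"p1": ["D1", "D1"], "p2": ["D2"]}, {("p1", "p2"): 0.5})
    t = _table({("D1", "D2"): 0.5})
    assert predict_strength(ds.pairs[0], t, ds.proteins) == pytest.approx(0.75)


def test_combiner_reports_missing_keys():
    ds = make_dataset({"p1": ["D1", "D2"], "p2": ["D3"]}, {("p1", "p2"): 0.5})
    with pytest.raises(KeyError, match="D2"):
        predict_strength(ds.pairs[0], _table({("D1", "D3"): 0.5}), ds.proteins)


def test_combiner_is_accurate_for_tiny_factors():
    # factors within 1e-12 of 1 must not underflow to a wrong product
    ds = make_dataset({"p1": ["D1", "D2"], "p2": ["D3"]}, {("p1", "p2"): 0.5})
    t = _table({("D1", "D3"): 1 - 1e-13, ("D2", "D3"): 1 - 1e-13})
    expected = 1.0 - (1e-13) ** 2
    assert predict_strength(ds.pairs[0], t, ds.proteins) == pytest.approx(
        expected, rel=1e-9
    )


def test_combiner_matches_brute_force_and_is_monotone():
    rng = random.Random(31)
    for _ in range(25):
        ds = random_dataset(rng, n_proteins=10, n_pairs=12)
        table = asnm_scores(ds)
        for pair in ds.pairs:
            ref = brute_force_combine(pair, table.scores, ds.proteins)
            got = predict_strength(pair, table, ds.proteins)
            assert got == pytest.approx(ref, abs=1e-9)
            # raising one entry never lowers the prediction
            key = rng.choice(sorted(enumerate_domain_pairs(pair, ds.proteins)))
            bumped = dict(table.scores)
            bumped[key] = min(1.0, bumped[key] + 0.1)
            t2 = DDIScoreTable(bumped, "ASNM", dict(table.counts))
            assert predict_strength(pair, t2, ds.proteins) >= got - 1e-12


# -- coverage filter ---------------------------------------------------------

def test_coverage_filter_partitions_exactly():
    ds = make_dataset(
        {"p1": ["D1"], "p2": ["D2"], "p3": ["D1", "D3"]},
        {("p1", "p2"): 0.5, ("p2", "p3"): 0.5},
    )
    t = _table({("D1", "D2"): 0.5})
    kept, dropped = coverage_filter(ds.pairs, t, ds.proteins)
    assert [p.key for p in kept] == [("p1", "p2")]
    # (p2, p3) has (D2, D3) unscored among its pairs -> dropped wholesale
    assert [p.key for p in dropped] == [("p2", "p3")]
    assert len(kept) + len(dropped) == len(ds.pairs)


def test_coverage_filter_drops_domain_free_pairs():
    ds = make_dataset({"p1": [], "p2": ["D1"]}, {("p1", "p2"): 0.5})
    kept, dropped = coverage_filter(ds.pairs, _table({("D1", "D1"): 0.5}), ds.proteins)
    assert kept == [] and len(dropped) == 1
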