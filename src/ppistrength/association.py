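"""Domain-pair interaction scoring and the probabilistic strength combiner.

Under the domain-based model of protein interaction, two proteins interact
iff at least one pair of their constituent domains interacts. If each domain
pair (D_m, D_n) interacts independently with probability p(D_m, D_n), the
probability that proteins P_i and P_j interact is

    Pr(P_ij = 1) = 1 - prod_{D_m in P_i, D_n in P_j} (1 - p(D_m, D_n)),

where the product runs over domain *instance* pairs, so repeated domains
contribute repeated factors.

Three association-style estimators of p(D_m, D_n) from observed pair data
are provided:

* ASSOC — fraction of supporting protein pairs that interact (binary labels);
* ASNM  — mean interaction strength over supporting protein pairs;
* APM   — mean of the exponent-corrected strength
          1 - (1 - rho_ij)^(1 / (|P_i| |P_j|)), which inverts the product
          formula above under the assumption that all domain pairs of a
          protein pair contribute equally.

A protein pair (P_i, P_j) supports the domain pair (D_m, D_n) when the two
domains occur on opposite proteins in either orientation; each protein pair
is counted once per domain pair it supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .data_model import PairDataset, PairRecord

__all__ = [
    "DDIScoreTable",
    "domain_pair_key",
    "enumerate_domain_pairs",
    "assoc_scores",
    "asnm_scores",
    "apm_scores",
    "predict_strength",
    "coverage_filter",
    "write_score_table",
    "read_score_table",
]

DomainPair = tuple[str, str]


def domain_pair_key(m: str, n: str) -> DomainPair:
    """Canonical key for an unordered domain pair; (D, D) is legal."""
    return (m, n) if m <= n else (n, m)


@dataclass
class DDIScoreTable:
    """Estimated interaction probabilities for unordered domain pairs.

    Only domain pairs with at least one supporting protein pair are present;
    absence means "no evidence", not probability zero.
    """

    scores: dict[DomainPair, float]
    method: str
    counts: dict[DomainPair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} for domain pair {key} outside [0, 1]")
        for key, c in self.counts.items():
            if c < 1:
                raise ValueError(f"support count {c} for {key} must be >= 1")

    def __contains__(self, key: DomainPair) -> bool:
        return domain_pair_key(*key) in self.scores

    def __getitem__(self, key: DomainPair) -> float:
        return self.scores[domain_pair_key(*key)]

    def __len__(self) -> int:
        return len(self.scores)

    def keys(self):
        return self.scores.keys()


def enumerate_domain_pairs(pair: PairRecord, proteins) -> set[DomainPair]:
    """All unordered domain pairs formed across the two proteins of a pair.

    Distinct-id semantics: repeated instances do not create duplicate keys,
    and (D, D) appears when the same domain id occurs on both proteins.
    """
    da = proteins[pair.protein_a].distinct_domains
    db = proteins[pair.protein_b].distinct_domains
    return {domain_pair_key(m, n) for m in da for n in db}


def _accumulate(training: PairDataset, contribution) -> tuple[dict, dict]:
    sums: dict[DomainPair, float] = {}
    counts: dict[DomainPair, int] = {}
    for pr in training.pairs:
        value = contribution(pr)
        for key in enumerate_domain_pairs(pr, training.proteins):
            sums[key] = sums.get(key, 0.0) + value
            counts[key] = counts.get(key, 0) + 1
    return sums, counts


def assoc_scores(training: PairDataset) -> DDIScoreTable:
    """ASSOC: fraction of supporting pairs that interact. Requires binary strengths."""
    for pr in training.pairs:
        if pr.strength not in (0.0, 1.0):
            raise ValueError(
                f"ASSOC requires binary strengths; pair {pr.key} has {pr.strength}"
            )
    sums, counts = _accumulate(training, lambda pr: pr.strength)
    scores = {k: sums[k] / counts[k] for k in sums}
    return DDIScoreTable(scores, "ASSOC", counts)


def asnm_scores(training: PairDataset) -> DDIScoreTable:
    """ASNM: mean strength over supporting protein pairs."""
    sums, counts = _accumulate(training, lambda pr: pr.strength)
    scores = {k: sums[k] / counts[k] for k in sums}
    return DDIScoreTable(scores, "ASNM", counts)


def apm_scores(training: PairDataset, distinct_domains: bool = False) -> DDIScoreTable:
    """APM: mean exponent-corrected strength over supporting protein pairs.

    The correction divides each strength's "responsibility" evenly among the
    |P_i| * |P_j| domain instance pairs of the supporting protein pair. With
    ``distinct_domains`` the exponent counts distinct domain ids instead of
    instances.
    """

    def contribution(pr: PairRecord) -> float:
        ci = training.proteins[pr.protein_a].domain_count(distinct=distinct_domains)
        cj = training.proteins[pr.protein_b].domain_count(distinct=distinct_domains)
        if ci == 0 or cj == 0:
            raise ValueError(
                f"pair {pr.key} involves a protein without domains; "
                "the APM exponent 1/(|Pi||Pj|) is undefined"
            )
        return 1.0 - (1.0 - pr.strength) ** (1.0 / (ci * cj))

    sums, counts = _accumulate(training, contribution)
    scores = {k: sums[k] / counts[k] for k in sums}
    return DDIScoreTable(scores, "APM", counts)


def predict_strength(pair: PairRecord, table: DDIScoreTable, proteins) -> float:
    """Combine domain-pair scores into a predicted pair strength.

    Evaluates 1 - prod (1 - score) over all domain instance pairs, so a
    domain occurring twice contributes two factors. All instance pairs must
    be scored in the table (enforce upstream with :func:`coverage_filter`).
    Accumulation is done in log space, keeping the result accurate even when
    individual factors are within 1e-12 of 1.
    """
    ids_a = proteins[pair.protein_a].domain_ids
    ids_b = proteins[pair.protein_b].domain_ids
    missing = sorted(
        {
            domain_pair_key(m, n)
            for m in ids_a
            for n in ids_b
            if (m, n) not in table
        }
    )
    if missing:
        raise KeyError(f"pair {pair.key}: unscored domain pairs {missing}")
    log_miss = 0.0
    for m in ids_a:
        for n in ids_b:
            s = table[(m, n)]
            if s >= 1.0:
                return 1.0
            log_miss += math.log1p(-s)
    return -math.expm1(log_miss)


def coverage_filter(
    test_pairs: list[PairRecord], table: DDIScoreTable, proteins
) -> tuple[list[PairRecord], list[PairRecord]]:
    """Split test pairs into (kept, dropped) by score-table coverage.

    A pair is kept iff *every* domain pair it consists of has a score in the
    table; pairs of domain-free proteins have no scoreable domain pair and
    are dropped.
    """
    kept: list[PairRecord] = []
    dropped: list[PairRecord] = []
    for pr in test_pairs:
        pairs = enumerate_domain_pairs(pr, proteins)
        if pairs and all(key in table for key in pairs):
            kept.append(pr)
        else:
            dropped.append(pr)
    return kept, dropped


def write_score_table(table: DDIScoreTable, path) -> None:
    """Serialize as TSV: domain_a, domain_b (sorted), score, support_count."""
    with open(path, "w") as fh:
        fh.write("domain_a\tdomain_b\tscore\tsupport_count\n")
        for (m, n) in sorted(table.scores):
            count = table.counts.get((m, n), 1)
            fh.write(f"{m}\t{n}\t{float(table.scores[(m, n)])!r}\t{count}\n")


def read_score_table(path, method: str = "APM") -> DDIScoreTable:
    scores: dict[DomainPair, float] = {}
    counts: dict[DomainPair, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["domain_a", "domain_b", "score"]:
            raise ValueError(f"unexpected score table header {header!r}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            key = domain_pair_key(fields[0], fields[1])
            scores[key] = float(fields[2])
            counts[key] = int(fields[3]) if len(fields) > 3 else 1
    return DDIScoreTable(scores, method, counts)
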