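"""Synthetic benchmark generator with planted domain-interaction structure.

The generator emulates a weighted-interactome benchmark: a set of
proteins, each composed of a few domain instances embedded in a random
amino-acid sequence, and a list of unordered protein pairs whose strengths
are produced by the noisy-OR combination of a planted domain-pair
interaction probability matrix,

    clean(P_i, P_j) = 1 - prod over instance pairs (1 - p(D_m, D_n)),

optionally perturbed by truncated Gaussian noise and augmented with a set
of absent pairs at strength 0 as negative examples.

Because the planted matrix is returned alongside the dataset, estimator
recovery can be checked exactly: with single-domain proteins and no noise,
the mean-strength and exponent-corrected domain-pair estimators reproduce
the planted probabilities identically.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .association import domain_pair_key, write_score_table, DDIScoreTable
from .data_model import (
    AnnotatedProtein,
    DomainInstance,
    PairDataset,
    PairRecord,
    add_zero_pairs,
    pair_key,
    write_dataset,
)

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "generate",
    "reference_shape_config",
    "write_truth",
    "simulate_to_dir",
]

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AMBIGUOUS = "BZJXUO"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    Defaults describe a small but structurally realistic instance: proteins
    carry 1-4 domain instances of 40-120 residues separated by 5-30 residue
    linkers, 30% of domain pairs interact with a right-skewed Beta(2, 5)
    probability, strengths carry sd-0.05 truncated Gaussian noise, and a
    tenth of the emitted pairs are absent pairs at strength 0.
    """

    n_proteins: int = 60
    n_domains: int = 20
    n_pairs: int = 120
    domains_per_protein: tuple[int, int] = (1, 4)
    domain_length: tuple[int, int] = (40, 120)
    linker_length: tuple[int, int] = (5, 30)
    ddi_density: float = 0.3
    noise_sd: float = 0.05
    zero_pair_count: int = 12
    seed: int = 0
    repeat_prob: float = 0.1  # chance a slot repeats a domain already on the protein
    ambiguity_rate: float = 0.02  # per-residue chance of an ambiguity code
    # domain family sizes are heavy-tailed in real proteomes; domain draws
    # follow p(rank) ~ rank^-popularity_exponent (0 = uniform)
    popularity_exponent: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_domains, self.n_pairs) <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.ddi_density <= 1.0):
            raise ValueError("ddi_density must lie in [0, 1]")
        if self.noise_sd < 0 or self.zero_pair_count < 0:
            raise ValueError("noise_sd and zero_pair_count must be non-negative")
        for lo, hi in (self.domains_per_protein, self.domain_length, self.linker_length):
            if lo < 0 or lo > hi:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")
        if self.domains_per_protein[0] < 1:
            raise ValueError("every protein needs at least one domain instance")


@dataclass
class PlantedTruth:
    """Ground truth behind a generated dataset.

    ``ddi_probabilities`` stores the nonzero planted probabilities (absent
    pairs have probability 0); ``clean_strengths`` maps each *modelled*
    protein pair (not the zero-augmented ones) to its noise-free strength.
    """

    ddi_probabilities: dict[tuple[str, str], float]
    clean_strengths: dict[tuple[str, str], float] = field(default_factory=dict)

    def probability(self, m: str, n: str) -> float:
        return self.ddi_probabilities.get(domain_pair_key(m, n), 0.0)

    def as_score_table(self) -> DDIScoreTable:
        return DDIScoreTable(dict(self.ddi_probabilities), "PLANTED",
                             {k: 1 for k in self.ddi_probabilities})


def _clean_strength(pa: AnnotatedProtein, pb: AnnotatedProtein, truth: PlantedTruth) -> float:
    log_miss = 0.0
    for m in pa.domain_ids:
        for n in pb.domain_ids:
            p = truth.probability(m, n)
            if p >= 1.0:
                return 1.0
            log_miss += math.log1p(-p)
    return -math.expm1(log_miss)


def _random_sequence(rng: np.random.Generator, length: int, ambiguity_rate: float) -> str:
    residues = rng.choice(list(_STANDARD_AA), size=length)
    mask = rng.random(length) < ambiguity_rate
    if mask.any():
        residues[mask] = rng.choice(list(_AMBIGUOUS), size=int(mask.sum()))
    return "".join(residues)


def generate(config: GeneratorConfig) -> tuple[PairDataset, PlantedTruth]:
    """Draw a full synthetic dataset and its ground truth.

    Proteins are built first (every universe domain is guaranteed to appear
    on at least one protein, which requires n_proteins >= n_domains), then a
    planted probability is drawn for a ``ddi_density`` fraction of domain
    pairs, and finally ``n_pairs`` distinct unordered protein pairs with
    positive clean strength are sampled as the weighted pair list. The whole
    construction is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    universe = [f"D{i+1:04d}" for i in range(config.n_domains)]

    # per-protein instance counts and repeat flags (first slot never repeats)
    counts = rng.integers(
        config.domains_per_protein[0], config.domains_per_protein[1] + 1,
        size=config.n_proteins,
    )
    repeat_flags = [
        [False] + [bool(rng.random() < config.repeat_prob) for _ in range(c - 1)]
        for c in counts
    ]
    n_fresh = sum(sum(not f for f in flags) for flags in repeat_flags)
    if n_fresh < config.n_domains:
        raise ValueError(
            f"only {n_fresh} fresh instance slots for {config.n_domains} domains; "
            "increase n_proteins or domains_per_protein"
        )
    ranks = np.arange(1, config.n_domains + 1, dtype=float)
    popularity = ranks ** -config.popularity_exponent
    popularity /= popularity.sum()
    stream = list(rng.permutation(universe)) + list(
        rng.choice(universe, size=n_fresh - config.n_domains, p=popularity)
    )
    pos = 0
    proteins: dict[str, AnnotatedProtein] = {}
    for i in range(config.n_proteins):
        pid = f"P{i+1:05d}"
        assigned: list[str] = []
        for flag in repeat_flags[i]:
            if flag and assigned:
                assigned.append(assigned[rng.integers(0, len(assigned))])
            else:
                assigned.append(stream[pos])
                pos += 1
        chunks: list[str] = []
        domains: list[DomainInstance] = []
        offset = 0
        for did in assigned:
            linker = _random_sequence(
                rng,
                int(rng.integers(config.linker_length[0], config.linker_length[1] + 1)),
                config.ambiguity_rate,
            )
            chunks.append(linker)
            offset += len(linker)
            dlen = int(rng.integers(config.domain_length[0], config.domain_length[1] + 1))
            region = _random_sequence(rng, dlen, config.ambiguity_rate)
            chunks.append(region)
            domains.append(DomainInstance(did, offset, offset + dlen))
            offset += dlen
        chunks.append(
            _random_sequence(
                rng,
                int(rng.integers(config.linker_length[0], config.linker_length[1] + 1)),
                config.ambiguity_rate,
            )
        )
        proteins[pid] = AnnotatedProtein(pid, "".join(chunks), domains)

    # planted domain-pair interaction probabilities
    ddi: dict[tuple[str, str], float] = {}
    for a in range(config.n_domains):
        for b in range(a, config.n_domains):
            if rng.random() < config.ddi_density:
                ddi[domain_pair_key(universe[a], universe[b])] = float(
                    rng.beta(2.0, 5.0)
                )
    truth = PlantedTruth(ddi)

    # sample distinct unordered protein pairs with positive clean strength
    ids = sorted(proteins)
    pairs: list[PairRecord] = []
    chosen: set[tuple[str, str]] = set()
    max_attempts = 2000 * config.n_pairs + 10000
    attempts = 0
    while len(pairs) < config.n_pairs:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not find enough protein pairs with positive clean strength; "
                "raise ddi_density or n_proteins"
            )
        i, j = rng.integers(0, len(ids), size=2)
        if i == j:
            continue
        key = pair_key(ids[i], ids[j])
        if key in chosen:
            continue
        clean = _clean_strength(proteins[key[0]], proteins[key[1]], truth)
        if clean <= 0.0:
            continue
        chosen.add(key)
        truth.clean_strengths[key] = clean
        if config.noise_sd > 0:
            strength = float(np.clip(clean + rng.normal(0.0, config.noise_sd), 0.0, 1.0))
        else:
            strength = clean
        pairs.append(PairRecord(key[0], key[1], strength))

    dataset = PairDataset(proteins, pairs)
    if config.zero_pair_count:
        zero_seed = int(rng.integers(0, 2**31 - 1))
        dataset = add_zero_pairs(dataset, config.zero_pair_count, zero_seed)
    return dataset, truth


def reference_shape_config(seed: int = 0) -> GeneratorConfig:
    """The reference benchmark shape: a curated yeast interactome extraction.

    758 proteins with 327 distinct domains, 1387 weighted pairs, and 100
    zero-strength pairs, for 1487 pairs in total — the scale at which the
    DN feature map is 654-dimensional.
    """
    return GeneratorConfig(
        n_proteins=758,
        n_domains=327,
        n_pairs=1387,
        zero_pair_count=100,
        ddi_density=0.05,
        seed=seed,
    )


def write_truth(truth: PlantedTruth, path) -> None:
    """Write the planted DDI matrix in the score-table TSV format."""
    write_score_table(truth.as_score_table(), path)


def simulate_to_dir(config: GeneratorConfig, out_dir) -> tuple[PairDataset, PlantedTruth]:
    """Generate and write seq.fa, dom.tsv, pairs.tsv and truth.tsv to a directory."""
    dataset, truth = generate(config)
    write_dataset(dataset, out_dir)
    write_truth(truth, os.path.join(out_dir, "truth.tsv"))
    return dataset, truth
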