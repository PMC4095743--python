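"""Shared builders for small hand-made datasets."""

from __future__ import annotations

import random

import pytest

from ppistrength.data_model import (
    AnnotatedProtein,
    DomainInstance,
    PairDataset,
    PairRecord,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_protein(pid: str, domain_ids: list[str], region_len: int = 6, rng=None) -> AnnotatedProtein:
    """A protein whose sequence is a chain of random regions, one per domain."""
    rng = rng or random.Random(hash(pid) & 0xFFFF)
    chunks, domains, offset = [], [], 0
    for did in domain_ids:
        linker = "".join(rng.choice(AA) for _ in range(3))
        chunks.append(linker)
        offset += len(linker)
        region = "".join(rng.choice(AA) for _ in range(region_len))
        chunks.append(region)
        domains.append(DomainInstance(did, offset, offset + region_len))
        offset += region_len
    if not chunks:
        chunks.append("".join(rng.choice(AA) for _ in range(10)))
    return AnnotatedProtein(pid, "".join(chunks), domains)


def make_dataset(compositions: dict[str, list[str]], strengths: dict[tuple[str, str], float]) -> PairDataset:
    """Dataset from {protein: [domain ids]} and {(a, b): strength}."""
    proteins = {pid: make_protein(pid, doms) for pid, doms in compositions.items()}
    pairs = [PairRecord(a, b, s) for (a, b), s in strengths.items()]
    return PairDataset(proteins, pairs)


def random_dataset(rng: random.Random, n_proteins: int = 8, n_domains: int = 5,
                   n_pairs: int = 10, binary: bool = False) -> PairDataset:
    """A random small dataset; every protein has 1-3 domain instances."""
    domain_ids = [f"D{i}" for i in range(1, n_domains + 1)]
    compositions = {
        f"p{i}": [rng.choice(domain_ids) for _ in range(rng.randint(1, 3))]
        for i in range(1, n_proteins + 1)
    }
    ids = sorted(compositions)
    all_pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    chosen = rng.sample(all_pairs, min(n_pairs, len(all_pairs)))
    strengths = {
        key: float(rng.randint(0, 1)) if binary else rng.random() for key in chosen
    }
    return make_dataset(compositions, strengths)


@pytest.fixture
def toy_dataset() -> PairDataset:
    """Four proteins, three domains, four weighted pairs."""
    return make_dataset(
        {"p1": ["D1", "D2"], "p2": ["D2", "D3"], "p3": ["D1"], "p4": ["D3", "D3"]},
        {("p1", "p2"): 0.8, ("p1", "p3"): 0.4, ("p2", "p3"): 0.0, ("p3", "p4"): 1.0},
    )
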