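"""Core data types and plain-text I/O for the PPI-strength pipeline.

The pipeline works on three kinds of input:

* amino-acid sequences (FASTA),
* per-protein domain annotations (TSV: protein_id, domain_id, start, end,
  with 1-based inclusive coordinates as in UniProt feature tables),
* weighted protein-pair lists (TSV: protein_a, protein_b, weight), in the
  style of weighted interactome releases such as WI-PHI.

Internally domain coordinates are stored 0-based half-open; the file
readers and writers convert. Protein pairs are unordered and are stored
under the lexicographically sorted id pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "DomainInstance",
    "AnnotatedProtein",
    "PairRecord",
    "PairDataset",
    "pair_key",
    "read_fasta",
    "write_fasta",
    "read_domain_annotations",
    "write_domain_annotations",
    "read_pair_weights",
    "write_pair_weights",
    "normalize_strengths",
    "add_zero_pairs",
    "read_pair_strengths",
    "write_pair_strengths",
    "write_dataset",
    "read_dataset",
]


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) key for an unordered protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DomainInstance:
    """One occurrence of a domain on a protein sequence.

    ``start``/``end`` are 0-based half-open internally; use
    :meth:`to_1based` when presenting coordinates to a user.
    """

    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid domain region [{self.start}, {self.end}) for {self.domain_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """Return the (start, end) pair in 1-based inclusive convention."""
        return self.start + 1, self.end


@dataclass
class AnnotatedProtein:
    """A protein: id, amino-acid sequence, and its ordered domain instances.

    The domain list is kept sorted by start position. The same domain id may
    occur several times (tandem repeats); ``multiplicity`` counts occurrences.
    """

    protein_id: str
    sequence: str
    domains: list[DomainInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda d: (d.start, d.end, d.domain_id))
        for d in self.domains:
            if d.end > len(self.sequence):
                raise ValueError(
                    f"domain {d.domain_id} on {self.protein_id} ends at "
                    f"{d.end} but sequence has length {len(self.sequence)}"
                )

    def multiplicity(self, domain_id: str) -> int:
        """Number of instances of ``domain_id`` on this protein (M(D, P))."""
        return sum(1 for d in self.domains if d.domain_id == domain_id)

    @property
    def domain_ids(self) -> list[str]:
        """Domain ids in order of appearance, with multiplicity."""
        return [d.domain_id for d in self.domains]

    @property
    def distinct_domains(self) -> set[str]:
        return {d.domain_id for d in self.domains}

    def domain_count(self, distinct: bool = False) -> int:
        """|P|: number of domain instances (or distinct domain ids)."""
        return len(self.distinct_domains) if distinct else len(self.domains)


@dataclass(frozen=True)
class PairRecord:
    """An unordered protein pair with a real-valued interaction strength in [0, 1]."""

    protein_a: str
    protein_b: str
    strength: float

    def __post_init__(self) -> None:
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError(
                f"strength {self.strength} for pair "
                f"({self.protein_a}, {self.protein_b}) outside [0, 1]"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def is_self(self) -> bool:
        """True for homodimer pairs (both endpoints the same protein)."""
        return self.protein_a == self.protein_b


@dataclass
class PairDataset:
    """Protein universe, unordered weighted pairs, and the induced domain universe.

    ``domain_universe`` is the sorted list of distinct domain ids appearing
    across all proteins; its length T fixes the indexing of the domain-count
    feature map.
    """

    proteins: dict[str, AnnotatedProtein]
    pairs: list[PairRecord]
    domain_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        appearing = sorted({d for p in self.proteins.values() for d in p.distinct_domains})
        if not self.domain_universe:
            self.domain_universe = appearing
        elif self.domain_universe != appearing:
            raise ValueError("domain_universe does not match the domains on the proteins")
        seen: set[tuple[str, str]] = set()
        for pr in self.pairs:
            if pr.protein_a not in self.proteins or pr.protein_b not in self.proteins:
                raise ValueError(f"pair {pr.key} references an unknown protein")
            if pr.key in seen:
                raise ValueError(f"duplicate unordered pair {pr.key}")
            seen.add(pr.key)

    @property
    def n_domains(self) -> int:
        return len(self.domain_universe)

    def strengths(self) -> np.ndarray:
        return np.array([p.strength for p in self.pairs], dtype=float)

    def subset(self, indices) -> "PairDataset":
        """A dataset with the same proteins but only the selected pairs."""
        return PairDataset(self.proteins, [self.pairs[i] for i in indices])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ["protein_id", "domain_id", "start", "end"]
_PAIR_COLUMNS = ["protein_a", "protein_b", "weight"]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{id: upper-case sequence}``.

    The id is the header token before the first whitespace. Duplicate ids and
    empty files are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_domain_annotations(path, sequences: dict[str, str]) -> list[AnnotatedProtein]:
    """Read the 4-column annotation TSV against the given sequences.

    Coordinates in the file are 1-based inclusive. Every protein in
    ``sequences`` is returned, those without annotation rows with an empty
    domain list. Out-of-bounds or inverted regions raise with the offending
    row number.
    """
    by_protein: dict[str, list[DomainInstance]] = {pid: [] for pid in sequences}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANNOT_COLUMNS:
            raise ValueError(
                f"expected header {_ANNOT_COLUMNS!r} in {path}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            pid, did, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable coordinates") from exc
            if pid not in sequences:
                raise ValueError(f"{path}:{lineno}: unknown protein {pid}")
            if start < 1 or start > end:
                raise ValueError(
                    f"{path}:{lineno}: invalid region {start}..{end} (1-based inclusive)"
                )
            if end > len(sequences[pid]):
                raise ValueError(
                    f"{path}:{lineno}: region end {end} exceeds length "
                    f"{len(sequences[pid])} of {pid}"
                )
            by_protein[pid].append(DomainInstance(did, start - 1, end))
    return [
        AnnotatedProtein(pid, sequences[pid], by_protein[pid]) for pid in sequences
    ]


def write_domain_annotations(proteins, path) -> None:
    if isinstance(proteins, dict):
        proteins = proteins.values()
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for p in proteins:
            for d in p.domains:
                s1, e1 = d.to_1based()
                fh.write(f"{p.protein_id}\t{d.domain_id}\t{s1}\t{e1}\n")


def read_pair_weights(path) -> list[tuple[str, str, float]]:
    """Read the 3-column weighted pair TSV, preserving input order.

    Weights must be non-negative reals; a duplicate unordered pair is an
    error. Self-pairs (homodimers) are accepted.
    """
    out: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PAIR_COLUMNS and header[:2] != _PAIR_COLUMNS[:2]:
            raise ValueError(f"expected header {_PAIR_COLUMNS!r} in {path}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            a, b, w_s = fields
            try:
                w = float(w_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable weight {w_s!r}") from exc
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"{path}:{lineno}: weight must be a non-negative real, got {w_s}")
            key = pair_key(a, b)
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate unordered pair {key}")
            seen.add(key)
            out.append((a, b, w))
    return out


def write_pair_weights(weights: list[tuple[str, str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLUMNS) + "\n")
        for a, b, w in weights:
            fh.write(f"{a}\t{b}\t{float(w)!r}\n")


def read_pair_strengths(path) -> list[PairRecord]:
    """Read a pair TSV whose third column already holds strengths in [0, 1]."""
    return [PairRecord(a, b, w) for a, b, w in read_pair_weights(path)]


def write_pair_strengths(pairs: list[PairRecord], path) -> None:
    write_pair_weights([(p.protein_a, p.protein_b, p.strength) for p in pairs], path)


def normalize_strengths(weights: list[tuple[str, str, float]]) -> list[PairRecord]:
    """Turn raw edge weights into strengths by dividing by the maximum weight.

    The largest weight maps to strength exactly 1. All-zero weight lists are
    rejected (the scale would be undefined).
    """
    if not weights:
        raise ValueError("empty weight list")
    wmax = max(w for _, _, w in weights)
    if wmax <= 0:
        raise ValueError("all weights are zero; cannot normalize")
    return [PairRecord(a, b, w / wmax) for a, b, w in weights]


def add_zero_pairs(dataset: PairDataset, n: int, seed: int) -> PairDataset:
    """Augment a dataset with ``n`` absent protein pairs at strength 0.

    Pairs are drawn uniformly without replacement from the unordered
    distinct-protein pairs not already present, reproducibly under ``seed``.
    Mirrors the construction of negative examples from an interactome whose
    edge list only contains weighted (interacting) pairs.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return dataset
    ids = sorted(dataset.proteins)
    existing = {p.key for p in dataset.pairs}
    rng = np.random.default_rng(seed)
    n_all = len(ids) * (len(ids) - 1) // 2
    n_absent = n_all - sum(1 for k in existing if k[0] != k[1])
    if n > n_absent:
        raise ValueError(f"requested {n} zero pairs but only {n_absent} absent pairs exist")
    if n_all <= 200_000:
        absent = [
            pair_key(a, b)
            for a, b in itertools.combinations(ids, 2)
            if pair_key(a, b) not in existing
        ]
        chosen_idx = rng.choice(len(absent), size=n, replace=False)
        chosen = [absent[i] for i in sorted(chosen_idx)]
    else:  # rejection sampling against the (sparse) existing edge set
        chosen_set: set[tuple[str, str]] = set()
        while len(chosen_set) < n:
            i, j = rng.integers(0, len(ids), size=2)
            if i == j:
                continue
            key = pair_key(ids[i], ids[j])
            if key in existing or key in chosen_set:
                continue
            chosen_set.add(key)
        chosen = sorted(chosen_set)
    new_pairs = dataset.pairs + [PairRecord(a, b, 0.0) for a, b in chosen]
    return PairDataset(dataset.proteins, new_pairs)


# ---------------------------------------------------------------------------
# whole-dataset round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: PairDataset, out_dir) -> None:
    """Write seq.fa, dom.tsv and pairs.tsv for a dataset into ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    seqs = {pid: p.sequence for pid, p in dataset.proteins.items()}
    write_fasta(seqs, os.path.join(out_dir, "seq.fa"))
    write_domain_annotations(dataset.proteins, os.path.join(out_dir, "dom.tsv"))
    write_pair_strengths(dataset.pairs, os.path.join(out_dir, "pairs.tsv"))


def read_dataset(in_dir) -> PairDataset:
    """Inverse of :func:`write_dataset`."""
    import os

    seqs = read_fasta(os.path.join(in_dir, "seq.fa"))
    proteins = read_domain_annotations(os.path.join(in_dir, "dom.tsv"), seqs)
    pairs = read_pair_strengths(os.path.join(in_dir, "pairs.tsv"))
    return PairDataset({p.protein_id: p for p in proteins}, pairs)
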