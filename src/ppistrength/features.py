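"""Feature space mappings from a protein pair to a numeric vector.

Three mappings are supported:

* DN    — domain-count features: the multiplicity of every domain of the
          universe on each of the two proteins, dimension 2T for a
          T-domain universe.
* SPD   — domain-restricted k-spectrum features: k-mer counts over the
          concatenation of each protein's domain subsequences, on a
          21-letter alphabet (20 standard amino acids plus one catch-all
          for ambiguity codes), dimension 2 * 21**k.
* APM   — the scalar combined strength predicted from an APM domain-pair
          score table, dimension 1.

Pairs are unordered; each pair is put into canonical (lexicographic) order
before mapping, so swapping the two proteins yields the identical vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import DDIScoreTable, predict_strength
from .data_model import AnnotatedProtein, PairRecord

__all__ = [
    "Alphabet21",
    "DEFAULT_ALPHABET",
    "FeatureMatrix",
    "dn_features",
    "restrict_to_domains",
    "kmer_counts",
    "spd_features",
    "apm_feature",
    "feature_matrix",
]

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet21:
    """20 standard amino acids plus a single catch-all symbol.

    Ambiguity and non-standard codes (B, Z, J, X, U, O, gaps, anything else)
    all map onto the final symbol, written 'X'. The mapping from raw
    characters is total.
    """

    symbols: tuple[str, ...] = tuple(_STANDARD_AA) + ("X",)

    def __post_init__(self) -> None:
        if len(self.symbols) != 21 or len(set(self.symbols)) != 21:
            raise ValueError("alphabet must contain exactly 21 distinct symbols")

    @property
    def size(self) -> int:
        return 21

    def index(self, ch: str) -> int:
        try:
            return self.symbols.index(ch.upper())
        except ValueError:
            return len(self.symbols) - 1

    def encode(self, s: str) -> np.ndarray:
        """Map a raw string to symbol indices (vectorised, total)."""
        lut = np.full(256, len(self.symbols) - 1, dtype=np.int64)
        for i, sym in enumerate(self.symbols):
            lut[ord(sym)] = i
            lut[ord(sym.lower())] = i
        raw = np.frombuffer(s.encode("latin-1", errors="replace"), dtype=np.uint8)
        return lut[raw]


DEFAULT_ALPHABET = Alphabet21()


@dataclass
class FeatureMatrix:
    """Per-pair feature vectors with a declared dimension and mapping name."""

    vectors: np.ndarray
    dimension: int
    mapping_name: str
    pair_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.dimension:
            raise ValueError(
                f"feature vectors have shape {self.vectors.shape}, "
                f"expected (*, {self.dimension})"
            )
        if self.pair_ids and len(self.pair_ids) != self.vectors.shape[0]:
            raise ValueError("pair_ids length does not match the number of vectors")


def _ordered(pair: PairRecord, proteins) -> tuple[AnnotatedProtein, AnnotatedProtein]:
    # PairRecord already stores the canonical (sorted) orientation
    return proteins[pair.protein_a], proteins[pair.protein_b]


def dn_features(pair: PairRecord, proteins, domain_universe: list[str]) -> np.ndarray:
    """Domain-count vector of length 2T.

    Entry m holds the multiplicity of universe domain m on the first protein
    of the canonically ordered pair, entry T+m the multiplicity on the
    second; domains absent from both contribute zeros.
    """
    index = {d: i for i, d in enumerate(domain_universe)}
    T = len(domain_universe)
    pa, pb = _ordered(pair, proteins)
    v = np.zeros(2 * T)
    for d in pa.domain_ids:
        if d not in index:
            raise KeyError(f"domain {d} not in the domain universe")
        v[index[d]] += 1
    for d in pb.domain_ids:
        if d not in index:
            raise KeyError(f"domain {d} not in the domain universe")
        v[T + index[d]] += 1
    return v


def restrict_to_domains(protein: AnnotatedProtein) -> str:
    """Concatenate the protein's domain subsequences in order of appearance.

    Overlapping regions are extracted independently (shared residues appear
    once per covering domain). A protein without domains maps to "".
    """
    return "".join(protein.sequence[d.start : d.end] for d in protein.domains)


def kmer_counts(s: str, k: int, alphabet: Alphabet21 = DEFAULT_ALPHABET) -> np.ndarray:
    """Count overlapping k-mer occurrences over the 21-symbol alphabet.

    Returns a vector of length 21**k whose entries sum to
    max(0, len(s) - k + 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    a = alphabet.size
    out_len = a**k
    if len(s) < k:
        return np.zeros(out_len)
    codes = alphabet.encode(s)
    # rolling base-21 index of each window
    idx = np.zeros(len(s) - k + 1, dtype=np.int64)
    for offset in range(k):
        idx = idx * a + codes[offset : offset + len(idx)]
    return np.bincount(idx, minlength=out_len).astype(float)


def spd_features(
    pair: PairRecord, proteins, k: int, alphabet: Alphabet21 = DEFAULT_ALPHABET
) -> np.ndarray:
    """Domain-restricted spectrum vector of length 2 * 21**k.

    k-mers are counted on each protein's concatenated domain subsequences;
    windows spanning the junction between consecutive domain regions count.
    """
    pa, pb = _ordered(pair, proteins)
    return np.concatenate(
        [
            kmer_counts(restrict_to_domains(pa), k, alphabet),
            kmer_counts(restrict_to_domains(pb), k, alphabet),
        ]
    )


def apm_feature(pair: PairRecord, table: DDIScoreTable, proteins) -> np.ndarray:
    """Length-1 vector holding the combined strength predicted from the table."""
    return np.array([predict_strength(pair, table, proteins)])


def feature_matrix(
    pairs: list[PairRecord],
    proteins,
    mapping: str,
    *,
    domain_universe: list[str] | None = None,
    k: int = 1,
    table: DDIScoreTable | None = None,
    alphabet: Alphabet21 = DEFAULT_ALPHABET,
) -> FeatureMatrix:
    """Stack per-pair vectors for one of the mappings {"dn", "spd", "apm"}."""
    mapping = mapping.lower()
    if mapping == "dn":
        if domain_universe is None:
            raise ValueError("dn mapping requires a domain_universe")
        rows = [dn_features(p, proteins, domain_universe) for p in pairs]
        dim, name = 2 * len(domain_universe), "DN"
    elif mapping == "spd":
        rows = [spd_features(p, proteins, k, alphabet) for p in pairs]
        dim, name = 2 * alphabet.size**k, f"SPD-{k}"
    elif mapping == "apm":
        if table is None:
            raise ValueError("apm mapping requires a DDI score table")
        rows = [apm_feature(p, table, proteins) for p in pairs]
        dim, name = 1, "APM"
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    vectors = np.vstack(rows) if rows else np.zeros((0, dim))
    return FeatureMatrix(vectors, dim, name, [p.key for p in pairs])
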