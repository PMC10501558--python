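"""Gapped nucleotide-pair ("distance") profiles.

For a gap size k, the sequence is scanned for every ordered pair of
positions (i, i+k+1) — first and last nucleotide separated by exactly k
intervening characters — and the 16 ordered pair cells (A..A through
T..T, lexicographic over (first, last)) are counted. The deployed
feature concatenates the 16-cell blocks for k = 0..k_max (default 8,
hence 9 x 16 = 144 dimensions). ``aggregate_pair_counts`` sums over
every admissible gap 0..L-2 instead, i.e. counts all position pairs
i < j; it serves as a diagnostic that matches hand-countable examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rnaloc.io import MrnaRecord
from rnaloc.kmer import NUCLEOTIDES, encode_sequence

#: Ordered pair names, lexicographic over (first, last): AxA, AxC, ... TxT.
PAIR_NAMES = [a + "x" + b for a in NUCLEOTIDES for b in NUCLEOTIDES]

DEFAULT_K_MAX = 8


@dataclass(frozen=True)
class DistancePairProfile:
    """Concatenated 16-cell gap-pair blocks for k = 0..k_max."""

    k_max: int
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        if len(self.values) != 16 * (self.k_max + 1):
            raise ValueError("profile must have 16*(k_max+1) entries")

    def block(self, k: int) -> np.ndarray:
        """The 16-cell block for gap size k."""
        if not 0 <= k <= self.k_max:
            raise IndexError(f"gap {k} outside 0..{self.k_max}")
        return self.values[16 * k : 16 * (k + 1)]


def pair_gap_counts(record: MrnaRecord, k: int) -> np.ndarray:
    """16-cell counts of ordered pairs (S[i], S[i+k+1]) for gap size k.

    Pairs with either endpoint ``N`` are skipped; a sequence shorter
    than k+2 yields a zero vector.
    """
    if k < 0:
        raise ValueError(f"gap size must be >= 0, got {k}")
    codes = encode_sequence(record.sequence)
    if len(codes) < k + 2:
        return np.zeros(16)
    first = codes[: -(k + 1)]
    last = codes[k + 1 :]
    valid = (first < 4) & (last < 4)
    idx = first[valid] * 4 + last[valid]
    return np.bincount(idx, minlength=16).astype(float)


def distance_profile(
    record: MrnaRecord, k_max: int = DEFAULT_K_MAX, normalized: bool = False
) -> DistancePairProfile:
    """Concatenate gap-pair blocks for k = 0..k_max (default 144-dim).

    Normalised mode divides every count by the sequence length L; the
    default is raw counts.
    """
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    values = np.concatenate([pair_gap_counts(record, k) for k in range(k_max + 1)])
    if normalized:
        values = values / record.length
    return DistancePairProfile(k_max=k_max, values=values, normalized=normalized)


def aggregate_pair_counts(record: MrnaRecord) -> np.ndarray:
    """16-cell counts over *all* position pairs i < j, any gap size.

    Cell (a, b) is the number of ordered pairs i < j with S[i] = a and
    S[j] = b, i.e. the sum of ``pair_gap_counts`` over gaps 0..L-2. For
    an N-free sequence the cells sum to L(L-1)/2.
    """
    codes = encode_sequence(record.sequence)
    counts = np.zeros((4, 4))
    prefix = np.zeros(4)  # occurrences of each nucleotide strictly before j
    for c in codes:
        if c < 4:
            counts[:, c] += prefix
            prefix[c] += 1
    return counts.ravel()


def distance_matrix(
    records: list[MrnaRecord], k_max: int = DEFAULT_K_MAX, normalized: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Stack per-record profiles into an (n, 16*(k_max+1)) matrix."""
    mat = np.stack([distance_profile(r, k_max, normalized).values for r in records])
    names = [f"k{k}_{a}{b}" for k in range(k_max + 1) for a in NUCLEOTIDES for b in NUCLEOTIDES]
    return mat, names


def pair_index(first: str, last: str) -> int:
    """Index of the ordered pair cell (first, last) in a 16-cell block."""
    return NUCLEOTIDES.index(first) * 4 + NUCLEOTIDES.index(last)
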