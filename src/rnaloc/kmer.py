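"""Lexicographic k-mer frequency profiles.

For a sequence S of length L, ``kmer_profile`` counts every width-k
sliding window (step 1) over the alphabet A<C<G<T in lexicographic
order, giving a 4^k vector. Normalised profiles divide each count by
the sequence length L. ``multi_kmer_profile`` concatenates the profiles
for a contiguous k range; the 1..5 range gives the 1364-dimensional
(4 + 16 + 64 + 256 + 1024) input used by the k-mer-only baseline
network.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from rnaloc.io import MrnaRecord

NUCLEOTIDES = "ACGT"
_CODE = np.full(128, 4, dtype=np.int64)  # 4 = sentinel for N / anything else
for _i, _c in enumerate(NUCLEOTIDES):
    _CODE[ord(_c)] = _i

MAX_K = 12  # dense 4^k storage guard


def encode_sequence(sequence: str) -> np.ndarray:
    """Integer-encode a sanitized sequence (A,C,G,T -> 0..3, N -> 4)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class KmerProfile:
    k: int
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        if len(self.values) != 4**self.k:
            raise ValueError(f"profile for k={self.k} must have 4^k entries")


@dataclass(frozen=True)
class MultiKmerProfile:
    k_min: int
    k_max: int
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        expected = sum(4**k for k in range(self.k_min, self.k_max + 1))
        if len(self.values) != expected:
            raise ValueError(f"multi-profile must have {expected} entries")


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k k-mers in strictly increasing lexicographic order (A<C<G<T)."""
    if k < 1 or k > MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    return ["".join(p) for p in product(NUCLEOTIDES, repeat=k)]


def _window_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic index of every N-free width-k window."""
    L = len(codes)
    if L < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ powers


def kmer_profile(record: MrnaRecord, k: int, normalized: bool = False) -> KmerProfile:
    """Count (or length-normalise) every width-k window of the sequence.

    Windows containing ``N`` are skipped. A sequence shorter than k
    yields an all-zero profile. Normalised mode divides raw counts by
    the sequence length L (not by the window count L-k+1).
    """
    if k < 1 or k > MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    codes = encode_sequence(record.sequence)
    counts = np.bincount(_window_indices(codes, k), minlength=4**k).astype(float)
    if normalized:
        counts /= record.length
    return KmerProfile(k=k, values=counts, normalized=normalized)


def multi_kmer_profile(
    record: MrnaRecord, k_min: int, k_max: int, normalized: bool = False
) -> MultiKmerProfile:
    """Concatenate k-mer profiles for k = k_min..k_max in increasing-k order."""
    if not 1 <= k_min <= k_max:
        raise ValueError(f"need 1 <= k_min <= k_max, got {k_min}..{k_max}")
    blocks = [kmer_profile(record, k, normalized).values for k in range(k_min, k_max + 1)]
    return MultiKmerProfile(
        k_min=k_min, k_max=k_max, values=np.concatenate(blocks), normalized=normalized
    )


def kmer_matrix(
    records: list[MrnaRecord], k: int, normalized: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Stack per-record profiles into an (n, 4^k) matrix; returns column names."""
    mat = np.stack([kmer_profile(r, k, normalized).values for r in records])
    return mat, enumerate_kmers(k)


def multi_kmer_matrix(
    records: list[MrnaRecord], k_min: int, k_max: int, normalized: bool = False
) -> tuple[np.ndarray, list[str]]:
    mat = np.stack(
        [multi_kmer_profile(r, k_min, k_max, normalized).values for r in records]
    )
    names = [m for k in range(k_min, k_max + 1) for m in enumerate_kmers(k)]
    return mat, names
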