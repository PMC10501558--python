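"""Reading and writing sequences, localization targets and PPI edge lists.

All sequence input is canonicalised to the DNA alphabet {A, C, G, T}
with ``N`` as the single ambiguity sentinel: RNA ``U`` becomes ``T``,
case is folded, and every IUPAC ambiguity code or stray symbol becomes
``N``. Downstream counters skip any window or pair touching an ``N``,
so ambiguous positions reduce the number of counted windows instead of
discarding whole records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_SANITIZE_TABLE = {}
for _c in "ACGTN":
    _SANITIZE_TABLE[ord(_c)] = _c
    _SANITIZE_TABLE[ord(_c.lower())] = _c
_SANITIZE_TABLE[ord("U")] = "T"
_SANITIZE_TABLE[ord("u")] = "T"


@dataclass(frozen=True)
class MrnaRecord:
    """A single mRNA: identifier plus sanitized nucleotide sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains unsanitized characters {sorted(bad)}; "
                "pass sequences through sanitize_sequence first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LocalizationTarget:
    """Localization targets for a corpus, keyed by mRNA id.

    In *continuous* mode each mRNA carries a probability vector over the
    compartments (renormalised to sum to 1 at load time); in *discrete*
    mode each mRNA carries a single compartment index.
    """

    mode: Literal["continuous", "discrete"]
    compartments: list[str]
    ids: list[str]
    values: np.ndarray  # (n, C) floats in continuous mode, (n,) ints in discrete

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        self.values = np.asarray(self.values)
        n = len(self.ids)
        if self.mode == "continuous":
            if self.values.shape != (n, len(self.compartments)):
                raise ValueError("continuous values must be (n_ids, n_compartments)")
            if (self.values < 0).any():
                raise ValueError("continuous target entries must be non-negative")
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("continuous target rows must sum to 1")
        else:
            if self.values.shape != (n,):
                raise ValueError("discrete values must be a flat index vector")
            if ((self.values < 0) | (self.values >= len(self.compartments))).any():
                raise ValueError("discrete label index out of range")

    def vector_for(self, mrna_id: str) -> np.ndarray:
        i = self.ids.index(mrna_id)
        if self.mode == "continuous":
            return self.values[i]
        out = np.zeros(len(self.compartments))
        out[self.values[i]] = 1.0
        return out

    def as_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Target matrix (one-hot encoded in discrete mode), rows in ``order``."""
        idx = {m: i for i, m in enumerate(self.ids)}
        order = list(order) if order is not None else self.ids
        missing = [m for m in order if m not in idx]
        if missing:
            raise KeyError(f"ids without targets: {missing[:5]}")
        rows = [idx[m] for m in order]
        if self.mode == "continuous":
            return self.values[rows]
        eye = np.eye(len(self.compartments))
        return eye[self.values[rows]]

    def labels_for(self, order: Sequence[str]) -> np.ndarray:
        """Discrete label indices (argmax of the vector in continuous mode)."""
        return np.argmax(self.as_matrix(order), axis=1)


@dataclass
class PpiEdgeList:
    """Weighted undirected edges between mRNA ids; no self-loops."""

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if w < 0:
                raise ValueError(f"negative weight on edge ({a},{b})")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge ({a},{b})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.edges)

    def node_ids(self) -> set[str]:
        return {a for a, _, _ in self.edges} | {b for _, b, _ in self.edges}


def sanitize_sequence(raw: str) -> str:
    """Canonicalise a nucleotide string to {A,C,G,T,N}.

    Uppercases, maps U to T, strips whitespace and replaces every other
    character (IUPAC ambiguity codes, gaps, digits) with the sentinel
    ``N``. Idempotent. Raises ``ValueError`` on an effectively empty
    input.
    """
    stripped = "".join(raw.split())
    if not stripped:
        raise ValueError("sequence is empty after stripping whitespace")
    return "".join(_SANITIZE_TABLE.get(ord(c), "N") for c in stripped)


def read_fasta(path: str | Path) -> list[MrnaRecord]:
    """Load a FASTA file into sanitized :class:`MrnaRecord` objects.

    The record id is the first whitespace-delimited token of the header;
    multi-line sequences are concatenated. Order is preserved. Raises on
    an empty file, a duplicate id or a record with an empty sequence.
    """
    path = Path(path)
    records: list[MrnaRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"record {entry.id!r} in {path} has an empty sequence")
        records.append(MrnaRecord(id=entry.id, sequence=sanitize_sequence(seq)))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[MrnaRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA (wrapped at ``width`` characters)."""
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(entries)


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; keeps one loader for CSV and TSV dialects
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def read_targets(
    path: str | Path,
    mode: Literal["continuous", "discrete"],
    compartments: Sequence[str],
) -> LocalizationTarget:
    """Load a localization-target table keyed by mRNA id.

    Continuous tables have one numeric column per compartment and are
    renormalised row-wise to sum to 1; discrete tables have a single
    label column validated against ``compartments``.
    """
    df = _read_table(path)
    compartments = list(compartments)
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in target table")
    if mode == "continuous":
        if df.shape[1] != len(compartments) + 1:
            raise ValueError(
                f"expected {len(compartments)} value columns, got {df.shape[1] - 1}"
            )
        values = df.iloc[:, 1:].astype(float).to_numpy()
        if (values < 0).any():
            bad = ids[int(np.argwhere(values < 0)[0, 0])]
            raise ValueError(f"negative target value for id {bad!r}")
        sums = values.sum(axis=1)
        if (sums <= 0).any():
            bad = ids[int(np.argmax(sums <= 0))]
            raise ValueError(f"target vector for id {bad!r} sums to 0")
        values = values / sums[:, None]
        return LocalizationTarget("continuous", compartments, ids, values)
    index = {name: i for i, name in enumerate(compartments)}
    labels = df.iloc[:, 1].astype(str).str.strip()
    unknown = sorted(set(labels) - set(index))
    if unknown:
        raise ValueError(f"unknown compartment name(s) {unknown}")
    values = np.array([index[l] for l in labels], dtype=np.int64)
    return LocalizationTarget("discrete", compartments, ids, values)


def write_targets(target: LocalizationTarget, path: str | Path) -> None:
    if target.mode == "continuous":
        df = pd.DataFrame(target.values, columns=target.compartments)
        df.insert(0, "id", target.ids)
    else:
        labels = [target.compartments[i] for i in target.values]
        df = pd.DataFrame({"id": target.ids, "label": labels})
    df.to_csv(path, sep="\t", index=False)


def read_ppi_edges(path: str | Path) -> PpiEdgeList:
    """Load a 3-column (id, id, weight) edge table.

    Self-loops are dropped with a warning; duplicate unordered pairs
    keep the maximum weight with a warning; a negative weight or a
    malformed row is an error naming the offending line. An empty file
    yields an empty edge list (no-PPI mode).
    """
    path = Path(path)
    best: dict[frozenset[str], tuple[str, str, float]] = {}
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace(",", "\t").split("\t") if p.strip()]
            if lineno == 1 and len(parts) == 3:
                try:
                    float(parts[2])
                except ValueError:
                    continue  # header row
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_w = parts
            try:
                w = float(raw_w)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: weight {raw_w!r} is not numeric") from exc
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            if a == b:
                n_self += 1
                continue
            key = frozenset((a, b))
            if key in best:
                n_dup += 1
                if w > best[key][2]:
                    best[key] = (a, b, w)
            else:
                best[key] = (a, b, w)
    if n_self:
        warnings.warn(f"{n_self} self-loop edge(s) dropped from {path}")
    if n_dup:
        warnings.warn(f"{n_dup} duplicate pair(s) in {path}; kept maximum weight")
    return PpiEdgeList(edges=sorted(best.values()))


def write_feature_tsv(
    ids: Sequence[str], values: np.ndarray, columns: Sequence[str], path: str | Path
) -> None:
    """Write an id-by-feature matrix as TSV with a header."""
    df = pd.DataFrame(np.asarray(values), columns=list(columns))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_feature_tsv(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read an id-by-feature TSV; returns (ids, matrix, column names)."""
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    return ids, df.iloc[:, 1:].to_numpy(dtype=float), list(df.columns[1:])
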