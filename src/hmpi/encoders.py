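"""Sequence encoders: one-hot matrices and dinucleotide structural profiles.

Two representations feed the two model branches:

* the 4 x L one-hot (quadrature) matrix, rows ordered (A, C, G, T);
* the 12 x (L-1) structural-profile (SP) matrix, obtained by sliding a 2-bp
  window over the sequence and looking up, for each of the 16 dinucleotides,
  twelve standardized physicochemical property values (A-philicity, base
  stacking, B-DNA twist, bendability, bending stiffness, DNA denaturation,
  duplex disrupt energy, duplex free energy, propeller twist, protein
  deformation, protein-DNA twist, Z-DNA propensity).

Each property row is standardized across the 16 dinucleotides (its exhaustive
population): ``std = (raw - mean) / population_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord

BASES = "ACGT"
#: The 16 dinucleotides in lexicographic order AA, AC, ..., TT.
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded (non-ACGT symbol, bad length)."""


@dataclass(frozen=True)
class StructuralPropertyTable:
    """12 properties x 16 dinucleotides, raw and (optionally) standardized."""

    property_names: tuple[str, ...]
    raw_values: np.ndarray          # (12, 16)
    std_values: np.ndarray | None = None  # (12, 16) after standardization

    def __post_init__(self) -> None:
        if self.raw_values.shape != (len(self.property_names), 16):
            raise ValueError(
                f"raw_values must be ({len(self.property_names)}, 16), "
                f"got {self.raw_values.shape}"
            )

    @property
    def n_properties(self) -> int:
        return len(self.property_names)


@dataclass(frozen=True)
class EncodedSample:
    """Model-ready encodings of one sequence."""

    source_id: str
    label: str
    onehot: np.ndarray | None = None     # (4, L) of {0,1}
    sp_matrix: np.ndarray | None = None  # (12, L-1) real


@dataclass(frozen=True)
class PositionalProfile:
    """Per-position mean standardized SP values over a set of sequences."""

    per_position_mean: np.ndarray  # (12, L-1)
    group: str
    n: int


def load_property_table(path: str | Path | None = None) -> StructuralPropertyTable:
    """Load the bundled dinucleotide property table, or a user override.

    The file format is tab-delimited: a header row with dinucleotide labels in
    lexicographic order, then 12 rows of ``property_name`` + 16 values.
    Comment lines start with ``#``.
    """
    if path is None:
        ref = resources.files("hmpi.data") / "structural_properties.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if tuple(df.columns) != DINUCLEOTIDES:
        raise ValueError(
            "property table columns must be the 16 dinucleotides in "
            f"lexicographic order {DINUCLEOTIDES}, got {tuple(df.columns)}"
        )
    return StructuralPropertyTable(
        property_names=tuple(df.index),
        raw_values=df.to_numpy(dtype=float),
    )


def standardize_table(table: StructuralPropertyTable) -> StructuralPropertyTable:
    """Standardize each property row across its 16 dinucleotide values.

    Uses the population standard deviation (the 16 dinucleotides are the
    full population, not a sample). A zero-variance row is an error.
    """
    raw = table.raw_values
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0.0)
    if flat.size:
        names = [table.property_names[i] for i in flat]
        raise ValueError(f"zero-variance property row(s): {names}")
    return replace(table, std_values=(raw - mean) / sd)


def _sequence_to_indices(record: SequenceRecord) -> np.ndarray:
    idx = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    out = np.full(idx.shape, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        out[idx == ord(base)] = i
    bad = np.flatnonzero(out < 0)
    if bad.size:
        pos = int(bad[0])
        raise EncodingError(
            f"record {record.id!r}: non-ACGT symbol "
            f"{record.sequence[pos]!r} at position {pos + 1}"
        )
    return out


def one_hot_encode(record: SequenceRecord) -> EncodedSample:
    """Encode a sequence as a 4 x L indicator matrix (rows A, C, G, T)."""
    idx = _sequence_to_indices(record)
    onehot = np.zeros((4, idx.size), dtype=np.float64)
    onehot[idx, np.arange(idx.size)] = 1.0
    return EncodedSample(source_id=record.id, label=record.label, onehot=onehot)


def sp_encode(record: SequenceRecord, table: StructuralPropertyTable) -> EncodedSample:
    """Encode a sequence as its 12 x (L-1) standardized structural profile.

    Column j holds the twelve standardized property values of the
    dinucleotide starting at position j (2-bp window, stride 1).
    """
    if table.std_values is None:
        raise ValueError("property table is not standardized; call standardize_table first")
    idx = _sequence_to_indices(record)
    if idx.size < 2:
        raise EncodingError(f"record {record.id!r}: length {idx.size} < 2, no dinucleotide")
    dinuc_idx = idx[:-1] * 4 + idx[1:]
    sp = table.std_values[:, dinuc_idx]
    return EncodedSample(source_id=record.id, label=record.label, sp_matrix=sp)


def encode_sample(record: SequenceRecord, table: StructuralPropertyTable) -> EncodedSample:
    """Produce both encodings for one record."""
    oh = one_hot_encode(record)
    sp = sp_encode(record, table)
    return EncodedSample(
        source_id=record.id, label=record.label, onehot=oh.onehot, sp_matrix=sp.sp_matrix
    )


def encode_dataset(
    records: Sequence[SequenceRecord], table: StructuralPropertyTable
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack encodings for same-length records.

    Returns ``(onehot, sp, labels)`` with shapes (n, 4, L), (n, 12, L-1) and
    the per-record label list in input order.
    """
    if not records:
        raise ValueError("no records to encode")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have mixed lengths {sorted(lengths)}")
    samples = [encode_sample(r, table) for r in records]
    onehot = np.stack([s.onehot for s in samples])
    sp = np.stack([s.sp_matrix for s in samples])
    return onehot, sp, [s.label for s in samples]


def positional_profile(
    records: Sequence[SequenceRecord],
    table: StructuralPropertyTable,
    group: str = "",
) -> PositionalProfile:
    """Mean standardized SP value at each position over a sequence set.

    The analogue of plotting average structural-property curves for promoters
    versus non-promoters: conserved elements show up as localized deviations
    from the ~0 background mean.
    """
    if not records:
        raise ValueError("positional_profile needs at least one record")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have mixed lengths {sorted(lengths)}")
    acc = np.zeros((table.n_properties, lengths.pop() - 1))
    for rec in records:
        acc += sp_encode(rec, table).sp_matrix
    return PositionalProfile(
        per_position_mean=acc / len(records), group=group, n=len(records)
    )
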