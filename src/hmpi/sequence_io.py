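"""Reading, validating, labelling and splitting fixed-length promoter windows.

The toolkit consumes pre-windowed FASTA: eukaryotic windows are 251 bp spanning
[-200, +50] around the TSS, prokaryotic windows 81 bp spanning [-60, +20].
Coordinates are metadata only; no genome extraction happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

#: Fraction of records held out for testing (the remaining 4/5 train).
TEST_FRACTION = 0.2


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or empty."""


class ValidationError(ValueError):
    """Raised when a sequence violates the alphabet or length contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled DNA sequence.

    ``label`` is an arbitrary class name: ``promoter``/``non-promoter`` in
    binary mode, or a sigma-factor subtype (``sigma24`` ... ``sigma70``).
    """

    id: str
    sequence: str
    label: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DatasetSplit:
    """A stratified train/test partition (4/5 train, 1/5 test)."""

    train: tuple[SequenceRecord, ...]
    test: tuple[SequenceRecord, ...]
    seed: int
    fractions: tuple[float, float] = (1.0 - TEST_FRACTION, TEST_FRACTION)


def _check_alphabet(seq: str) -> int | None:
    """Return the index of the first non-ACGT symbol, or None if clean."""
    for i, base in enumerate(seq):
        if base not in DNA_ALPHABET:
            return i
    return None


def read_fasta(path: str | Path, label: str, policy: str = "strict") -> list[SequenceRecord]:
    """Read a FASTA file and attach ``label`` to every entry.

    Sequences are uppercased on ingest. Under the default ``strict`` policy a
    non-ACGT symbol raises :class:`ValidationError` naming the record; under
    ``skip`` the offending record is dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such FASTA file: {path}")
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown ambiguity policy {policy!r}; use 'strict' or 'skip'")

    records: list[SequenceRecord] = []
    skipped = 0
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython raises ValueError on malformed input
        raise FastaParseError(f"malformed FASTA in {path}: {exc}") from exc
    if not entries:
        raise FastaParseError(f"FASTA file {path} contains no records")

    for entry in entries:
        seq = str(entry.seq).upper()
        bad = _check_alphabet(seq)
        if bad is not None:
            if policy == "strict":
                raise ValidationError(
                    f"record {entry.id!r}: non-ACGT symbol {seq[bad]!r} at position {bad + 1}"
                )
            skipped += 1
            continue
        records.append(SequenceRecord(id=entry.id, sequence=seq, label=label))
    if skipped:
        logger.info("read_fasta(%s): skipped %d record(s) with ambiguity codes", path, skipped)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as plain multi-FASTA with ``id|label`` headers."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}|{rec.label}\n{rec.sequence}\n")


def read_labelled_fasta(path: str | Path, policy: str = "strict") -> list[SequenceRecord]:
    """Read a FASTA whose headers encode the label as ``id|label``."""
    raw = read_fasta(path, label="", policy=policy)
    out = []
    for rec in raw:
        if "|" not in rec.id:
            raise FastaParseError(f"header {rec.id!r} lacks the 'id|label' format")
        rid, lab = rec.id.rsplit("|", 1)
        out.append(SequenceRecord(id=rid, sequence=rec.sequence, label=lab))
    return out


def validate_dataset(
    records: Sequence[SequenceRecord], expected_length: int, policy: str = "strict"
) -> list[SequenceRecord]:
    """Keep records of ``expected_length`` over ACGT; report rejections.

    Returns the surviving records; raises :class:`ValidationError` if none
    survive. The rejected count (with reasons) is logged.
    """
    survivors: list[SequenceRecord] = []
    rejected: dict[str, int] = {"length": 0, "non-ACGT": 0}
    for rec in records:
        if _check_alphabet(rec.sequence) is not None:
            rejected["non-ACGT"] += 1
            continue
        if len(rec) != expected_length:
            rejected["length"] += 1
            continue
        survivors.append(rec)
    n_rej = sum(rejected.values())
    if n_rej:
        logger.info(
            "validate_dataset: rejected %d record(s) (%d wrong length, %d non-ACGT)",
            n_rej, rejected["length"], rejected["non-ACGT"],
        )
    if not survivors:
        raise ValidationError(
            f"no records of length {expected_length} survived validation "
            f"({rejected['length']} wrong length, {rejected['non-ACGT']} non-ACGT)"
        )
    return survivors


def split_train_test(records: Sequence[SequenceRecord], seed: int) -> DatasetSplit:
    """Deterministic stratified 4/5-1/5 partition.

    Stratification keeps the test-set class balance stable; each class must
    contribute at least 5 records so that 1/5 of it is non-empty.
    """
    records = list(records)
    labels = [r.label for r in records]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    too_small = [lab for lab, c in counts.items() if c < 5]
    if too_small:
        raise ValueError(
            f"class(es) {too_small} have fewer than 5 records; a 1/5 hold-out "
            "needs >=5 per class (for rare subtypes, merge or resample upstream)"
        )
    train, test = train_test_split(
        records, test_size=TEST_FRACTION, random_state=seed, stratify=labels
    )
    return DatasetSplit(train=tuple(train), test=tuple(test), seed=seed)
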