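"""Synthetic labelled sequence datasets with plantable signals.

Two independent, controllable signal channels let every model be exercised
without any external download:

* a **positional motif** (default consensus ``TATAAT``) planted in positive
  sequences at a jittered offset, with per-position mutation — the local
  pattern a convolutional sequence branch should learn;
* a **dinucleotide-composition tilt**: positive backgrounds are drawn from a
  first-order Markov chain whose self-transition for a class-specific base is
  raised by ``composition_shift``, producing the kind of distributed
  dinucleotide bias a structural-profile branch should pick up through the
  SP encoding (the tilt is applied to transition frequencies, never to SP
  values directly).

Negatives are i.i.d. uniform over A/C/G/T. With mutation probability 1 and
zero shift, positives are statistically indistinguishable from negatives
(mutations draw uniformly over all four bases), which calibrates null
behaviour. The generator emulates promoter-versus-background discrimination
only; it makes no attempt at real promoter grammar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import SequenceRecord, write_fasta

BASES = np.array(list("ACGT"))

#: Class-size profile mirroring a realistic sigma-subtype imbalance
#: (sigma24, sigma28, sigma32, sigma38, sigma54, sigma70).
SUBTYPE_COUNTS = (484, 134, 291, 163, 94, 1694)
SUBTYPE_LABELS = ("sigma24", "sigma28", "sigma32", "sigma38", "sigma54", "sigma70")

#: Distinct per-class consensus motifs used in subtype layouts.
_SUBTYPE_MOTIFS = ("GGAACT", "CCGATA", "CTTGAA", "CTACAC", "TGGCAC", "TATAAT")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults give a clearly learnable binary task."""

    n_per_class: int = 1000
    length: int = 81
    motif: str = "TATAAT"
    mutation_prob: float = 0.1
    motif_position: int | None = None  # None: centred
    jitter: int = 2
    composition_shift: float = 0.2
    subtype_counts: tuple[int, ...] | None = None
    subtype_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if len(self.motif) > self.length:
            raise ValueError(
                f"motif of length {len(self.motif)} does not fit length {self.length}"
            )
        if not 0.0 <= self.composition_shift < 0.75:
            raise ValueError("composition_shift must keep transition rows on the simplex")
        if self.subtype_counts is not None:
            labels = self.subtype_labels or tuple(
                f"subtype_{i}" for i in range(len(self.subtype_counts))
            )
            if len(labels) != len(self.subtype_counts):
                raise ValueError("subtype_labels and subtype_counts must align")


def _markov_background(
    rng: np.random.Generator, n: int, length: int, tilt_base: int, shift: float
) -> np.ndarray:
    """Backgrounds with P(tilt_base -> tilt_base) and its complement raised.

    Both the tilted base and its Watson-Crick complement get a raised
    self-transition, so the bias is strand-symmetric (e.g. A and T tracts).
    """
    probs = np.full((4, 4), 0.25)
    comp = 3 - tilt_base  # A<->T, C<->G under the ACGT ordering
    for b in {tilt_base, comp}:
        probs[b] = 0.25 - shift / 3
        probs[b, b] = 0.25 + shift
    seqs = np.empty((n, length), dtype=np.int64)
    seqs[:, 0] = rng.integers(4, size=n)
    cum = probs.cumsum(axis=1)
    for j in range(1, length):
        u = rng.random(n)
        seqs[:, j] = (u[:, None] > cum[seqs[:, j - 1]]).sum(axis=1)
    return seqs


def _plant_motif(
    rng: np.random.Generator,
    seqs: np.ndarray,
    motif: str,
    position: int,
    jitter: int,
    mutation_prob: float,
) -> None:
    """Overwrite each row with a jittered, mutated copy of the motif.

    A mutated position is redrawn uniformly over all four bases, so
    ``mutation_prob = 1`` erases the signal completely.
    """
    base_idx = {b: i for i, b in enumerate("ACGT")}
    motif_idx = np.array([base_idx[b] for b in motif])
    m, length = len(motif_idx), seqs.shape[1]
    for row in seqs:
        off = position + int(rng.integers(-jitter, jitter + 1)) if jitter else position
        off = min(max(off, 0), length - m)
        planted = motif_idx.copy()
        mutate = rng.random(m) < mutation_prob
        planted[mutate] = rng.integers(4, size=int(mutate.sum()))
        row[off : off + m] = planted


def _to_records(seqs: np.ndarray, label: str, prefix: str) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=f"{prefix}{i}", sequence="".join(BASES[row]), label=label)
        for i, row in enumerate(seqs)
    ]


def generate(config: SyntheticConfig) -> list[SequenceRecord]:
    """Generate the dataset described by ``config`` (deterministic per seed).

    Binary layout (default): ``n_per_class`` positives labelled ``promoter``
    (motif + composition tilt) and ``n_per_class`` i.i.d. uniform negatives
    labelled ``non-promoter``. Subtype layout: one class per entry of
    ``subtype_counts``, each with its own consensus motif and its own tilted
    base, cycling through A/C/G/T.
    """
    rng = np.random.default_rng(config.seed)
    position = (
        config.motif_position
        if config.motif_position is not None
        else (config.length - len(config.motif)) // 2
    )

    if config.subtype_counts is None:
        pos = _markov_background(
            rng, config.n_per_class, config.length, tilt_base=0,
            shift=config.composition_shift,
        )
        _plant_motif(rng, pos, config.motif, position, config.jitter, config.mutation_prob)
        neg = rng.integers(4, size=(config.n_per_class, config.length))
        return _to_records(pos, "promoter", "pos_") + _to_records(neg, "non-promoter", "neg_")

    labels = config.subtype_labels or tuple(
        f"subtype_{i}" for i in range(len(config.subtype_counts))
    )
    records: list[SequenceRecord] = []
    for c, (count, label) in enumerate(zip(config.subtype_counts, labels)):
        motif = (
            _SUBTYPE_MOTIFS[c]
            if c < len(_SUBTYPE_MOTIFS)
            else "".join(BASES[rng.integers(4, size=len(config.motif))])
        )
        seqs = _markov_background(
            rng, count, config.length, tilt_base=c % 4, shift=config.composition_shift
        )
        _plant_motif(rng, seqs, motif, position, config.jitter, config.mutation_prob)
        records += _to_records(seqs, label, f"{label}_")
    return records


def write_fixture(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Emit records as FASTA with ``id|label`` headers (round-trips)."""
    write_fasta(records, path)
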