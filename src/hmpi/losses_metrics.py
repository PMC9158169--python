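"""Objective functions and evaluation measures.

Losses
------
* categorical cross-entropy (CCE): ``-log p(y)``, the standard softmax loss;
* label-smoothing regularization (LSR): the CCE against a smoothed target
  that puts ``eps/K`` mass on every class and ``1 - eps + eps/K`` on the true
  one, i.e. ``-(1-eps) log p(y) - (eps/K) sum_k log p(k)``;
* joint centre loss: ``-log p(y) + lambda * ||x - c_y||^2``, which pulls each
  sample's feature vector toward its class centre to gain intraclass
  compactness on top of the softmax's interclass separation.

Metrics
-------
Sensitivity, specificity, accuracy and the Matthews correlation coefficient
from binary confusion counts, with one-vs-rest reports in multi-class
(sigma-subtype) mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Probabilities are floored here before logs so training losses stay finite.
LOG_FLOOR = 1e-12


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis (max-subtraction)."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("probability vector must be 1-D with K >= 2")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be nonnegative and sum to 1")
    return p


def cce_loss(p: np.ndarray, y: int) -> float:
    """Categorical cross-entropy ``-log p(y)`` with a documented floor."""
    p = _check_probs(p)
    return float(-np.log(max(p[y], LOG_FLOOR)))


def lsr_loss(p: np.ndarray, y: int, epsilon: float) -> float:
    """CCE against the label-smoothed target distribution.

    Equals :func:`cce_loss` exactly at ``epsilon == 0``; on a uniform ``p``
    it is ``ln K`` for any ``epsilon``.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    p = _check_probs(p)
    logs = np.log(np.maximum(p, LOG_FLOOR))
    k = p.size
    return float(-(1.0 - epsilon) * logs[y] - (epsilon / k) * logs.sum())


def smoothed_targets(y: int, k: int, epsilon: float) -> np.ndarray:
    """The LSR target distribution: ``eps/K`` everywhere, peak at ``y``."""
    q = np.full(k, epsilon / k)
    q[y] += 1.0 - epsilon
    return q


@dataclass
class CentreSet:
    """Class centres (K x feature_dim) and the centre-loss weight lambda."""

    centres: np.ndarray
    lam: float = 0.01

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        if self.centres.ndim != 2:
            raise ValueError("centres must be a (K, feature_dim) matrix")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def joint_loss(p: np.ndarray, y: int, x: np.ndarray, centres: CentreSet) -> float:
    """Softmax loss plus lambda times squared distance to the class centre."""
    x = np.asarray(x, dtype=float)
    if x.shape != centres.centres[y].shape:
        raise ValueError(
            f"feature dim {x.shape} does not match centre dim {centres.centres[y].shape}"
        )
    d = x - centres.centres[y]
    return cce_loss(p, y) + centres.lam * float(d @ d)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and the derived Sn/Sp/Acc/Mcc."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_degenerate: bool = False
    per_class: dict[object, "EvaluationReport"] | None = None

    def summary(self) -> str:
        """Four-decimal report, percentages for Sn/Sp/Acc like field tables."""
        lines = [
            f"Sn(%)\t{100 * self.sn:.4f}",
            f"Sp(%)\t{100 * self.sp:.4f}",
            f"Acc(%)\t{100 * self.acc:.4f}",
            f"Mcc\t{self.mcc:.4f}",
        ]
        if self.per_class:
            for lab, rep in self.per_class.items():
                lines.append(f"{lab}\tAcc(%) {100 * rep.acc:.4f}\tMcc {rep.mcc:.4f}")
        return "\n".join(lines)


def confusion_report(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """Build a report from the four binary confusion counts."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion table")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    if degenerate:
        # Convention: a zero marginal makes Mcc undefined; report 0 and flag it.
        warnings.warn("Mcc denominator is zero; reporting 0", RuntimeWarning, stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn, sn=sn, sp=sp, acc=acc,
        mcc=float(mcc), mcc_degenerate=degenerate,
    )


def evaluate(
    predictions: Sequence[object],
    truths: Sequence[object],
    positive_class: object,
    classes: Sequence[object] | None = None,
) -> EvaluationReport:
    """Score predictions against truths.

    Binary: ``positive_class`` defines tp/fn, everything else is negative.
    If ``classes`` lists more than two labels, a one-vs-rest sub-report is
    produced per class (``per_class``), with the top-level report for
    ``positive_class``.
    """
    if len(predictions) != len(truths) or not truths:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    classes = list(classes) if classes is not None else sorted(
        set(truths) | set(predictions), key=repr
    )
    for v in list(predictions) + list(truths):
        if v not in classes:
            raise ValueError(f"label {v!r} outside the class set {classes}")
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in {classes}")

    def one_vs_rest(pos: object) -> EvaluationReport:
        tp = sum(1 for p, t in zip(predictions, truths) if t == pos and p == pos)
        fn = sum(1 for p, t in zip(predictions, truths) if t == pos and p != pos)
        fp = sum(1 for p, t in zip(predictions, truths) if t != pos and p == pos)
        tn = sum(1 for p, t in zip(predictions, truths) if t != pos and p != pos)
        return confusion_report(tp=tp, tn=tn, fp=fp, fn=fn)

    top = one_vs_rest(positive_class)
    if len(classes) > 2:
        per = {c: one_vs_rest(c) for c in classes}
        top = EvaluationReport(
            tp=top.tp, tn=top.tn, fp=top.fp, fn=top.fn, sn=top.sn, sp=top.sp,
            acc=top.acc, mcc=top.mcc, mcc_degenerate=top.mcc_degenerate, per_class=per,
        )
    return top
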