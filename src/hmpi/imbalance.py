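"""ADASYN adaptive synthetic oversampling in feature space.

For each minority sample, the fraction of majority points among its k nearest
neighbours measures how hard it is to learn; the synthetic budget
``G = (n_majority - n_minority) * balance_level`` is distributed across
minority samples proportionally to those difficulties, and each synthetic
row is drawn uniformly on the segment between a minority sample and one of
its k nearest minority neighbours.

Distances are Euclidean in z-scored feature space (learned features are
mixed-scale); the z-transform is inverted before returning synthetic rows,
so outputs live in the original space. Originals are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResamplingPlan:
    """Per-minority-sample synthetic budgets and difficulty weights."""

    k_neighbours: int
    balance_level: float
    minority_label: object
    per_sample_weights: np.ndarray  # r-hat, sums to 1 (uniform fallback)
    synth_counts: np.ndarray        # integers, one per minority sample
    duplication_fallback: bool = False

    @property
    def total(self) -> int:
        return int(self.synth_counts.sum())


def _zscore(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (features - mu) / sd, mu, sd


def plan_adasyn(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    balance_level: float = 1.0,
    minority_label: object | None = None,
) -> ResamplingPlan:
    """Compute the ADASYN synthetic budget for the minority class.

    ``labels`` is binary (minority vs rest); if ``minority_label`` is not
    given, the rarer label is used. Difficulty of minority sample i is
    ``r_i = (# majority among its k nearest neighbours in the full data)/k``;
    the normalized ``r-hat`` weights split ``G`` into integer per-sample
    counts. If all difficulties are zero (perfect separation) the weights
    fall back to uniform. A minority class too small for k distinct
    neighbours triggers a duplication fallback, flagged on the plan.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k_neighbours must be >= 1")
    if not 0.0 < balance_level <= 1.0:
        raise ValueError("balance_level must lie in (0, 1]")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"plan_adasyn needs exactly two label values, got {classes}")
    if minority_label is None:
        minority_label = classes[np.argmin(counts)]
    minority_mask = labels == minority_label
    n_min = int(minority_mask.sum())
    n_maj = int((~minority_mask).sum())
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes must be present")
    if n_min >= n_maj:
        raise ValueError("minority class is not smaller than the majority class")

    g = (n_maj - n_min) * balance_level
    minority_idx = np.flatnonzero(minority_mask)

    if n_min <= k:
        # too few minority points for a k-neighbourhood: duplicate evenly
        logger.warning(
            "minority class has %d <= k=%d samples; duplication fallback", n_min, k
        )
        weights = np.full(n_min, 1.0 / n_min)
        counts_ = _integerize(weights * g)
        return ResamplingPlan(
            k_neighbours=k, balance_level=balance_level,
            minority_label=minority_label, per_sample_weights=weights,
            synth_counts=counts_, duplication_fallback=True,
        )

    z, _, _ = _zscore(features)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    _, nbrs = nn.kneighbors(z[minority_idx])
    nbrs = nbrs[:, 1:]  # drop self
    r = (~minority_mask[nbrs]).sum(axis=1) / k
    if r.sum() == 0:
        weights = np.full(n_min, 1.0 / n_min)
    else:
        weights = r / r.sum()
    return ResamplingPlan(
        k_neighbours=k, balance_level=balance_level, minority_label=minority_label,
        per_sample_weights=weights, synth_counts=_integerize(weights * g),
    )


def _integerize(target: np.ndarray) -> np.ndarray:
    """Round per-sample budgets, fixing the total via largest remainders."""
    floor = np.floor(target).astype(int)
    remainder = target - floor
    deficit = int(round(target.sum())) - int(floor.sum())
    if deficit > 0:
        top = np.argsort(remainder)[::-1][:deficit]
        floor[top] += 1
    return floor


def synthesize(
    features: np.ndarray,
    labels: np.ndarray,
    plan: ResamplingPlan,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate the planned synthetic minority rows.

    Returns ``(features_aug, labels_aug, synthetic_flag)`` where the first
    ``len(features)`` rows are the untouched originals and the flag marks
    synthetic rows. Each synthetic row is ``x_i + u * (x_z - x_i)`` with
    ``u ~ U[0, 1]`` and ``x_z`` a random one of x_i's k nearest minority
    neighbours (or x_i itself under the duplication fallback). Deterministic
    for a fixed seed.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    minority_idx = np.flatnonzero(labels == plan.minority_label)
    if minority_idx.size != plan.synth_counts.size:
        raise ValueError("plan does not match the given labels")
    if plan.total == 0:
        return features, labels, np.zeros(len(labels), dtype=bool)

    rng = np.random.default_rng(seed)
    x_min = features[minority_idx]

    if plan.duplication_fallback or len(minority_idx) <= plan.k_neighbours:
        nbrs = None
    else:
        z, mu, sd = _zscore(features)
        nn = NearestNeighbors(n_neighbors=plan.k_neighbours + 1).fit(z[minority_idx])
        _, nbrs = nn.kneighbors(z[minority_idx])
        nbrs = nbrs[:, 1:]

    rows = []
    for i, count in enumerate(plan.synth_counts):
        for _ in range(int(count)):
            if nbrs is None:
                partner = x_min[i]
            else:
                partner = x_min[rng.choice(nbrs[i])]
            u = rng.random()
            rows.append(x_min[i] + u * (partner - x_min[i]))
    synth = np.vstack(rows)
    features_aug = np.vstack([features, synth])
    labels_aug = np.concatenate(
        [labels, np.full(len(rows), plan.minority_label, dtype=labels.dtype)]
    )
    flag = np.zeros(len(labels_aug), dtype=bool)
    flag[len(labels):] = True
    return features_aug, labels_aug, flag


def adasyn_per_class(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    balance_level: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance every class up toward the largest one, one minority at a time.

    Each class smaller than the largest is resampled against the union of all
    other classes (binary minority-vs-rest plan); synthetic rows accumulate.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    majority = classes[np.argmax(counts)]
    feats_aug = np.asarray(features, dtype=float)
    labs_aug = labels.copy()
    flags = np.zeros(len(labels), dtype=bool)
    for j, cls in enumerate(classes):
        if cls == majority:
            continue
        binary = np.where(labs_aug == cls, 1, 0)
        if (binary == 1).sum() >= (binary == 0).sum():
            continue
        plan = plan_adasyn(feats_aug, binary, k=k, balance_level=balance_level,
                           minority_label=1)
        # rescale the budget: targets parity with the majority class, not the rest
        n_cls = int((labs_aug == cls).sum())
        g = max(0, int(round((counts.max() - n_cls) * balance_level)))
        scaled = _integerize(plan.per_sample_weights * g)
        plan = ResamplingPlan(
            k_neighbours=plan.k_neighbours, balance_level=balance_level,
            minority_label=1, per_sample_weights=plan.per_sample_weights,
            synth_counts=scaled, duplication_fallback=plan.duplication_fallback,
        )
        feats_new, bin_new, flag_new = synthesize(feats_aug, binary, plan, seed + j)
        n_added = len(bin_new) - len(binary)
        feats_aug = feats_new
        labs_aug = np.concatenate([labs_aug, np.full(n_added, cls, dtype=labels.dtype)])
        flags = np.concatenate([flags, np.ones(n_added, dtype=bool)])
    return feats_aug, labs_aug, flags
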