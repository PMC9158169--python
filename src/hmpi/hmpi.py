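"""The hybrid model: fusing sequence and structural features.

The sequence branch (PSFN) and the structural branch (DSPN) each reduce a
sample to a feature vector; the two vectors are concatenated into one hybrid
feature, which a small dense layer plus a K-way softmax classifies.

Variants
--------
* ``base`` — the plain hybrid, head trained with CCE;
* ``lsr``  — identical architecture, head trained with label-smoothing CCE
  (``epsilon = 0.2``);
* ``at``   — for imbalanced subtype data: ADASYN oversampling applied in a
  transferred feature space (the PSFN's second convolution block output,
  global-average-pooled, concatenated with the DSPN structural features),
  because raw one-hot sequence matrices are not meaningfully interpolable.

The default training regime pretrains each branch on its own loss, freezes
them, and trains the fusion head on the extracted features; a joint
end-to-end regime is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import dspn as dspn_mod
from . import imbalance, nn
from . import psfn as psfn_mod

Variant = Literal["base", "at", "lsr"]
Regime = Literal["pretrain_then_head", "joint"]


@dataclass
class HmpiSpec:
    """Branch specs plus fusion-head and variant settings."""

    psfn_spec: psfn_mod.PsfnSpec = field(default_factory=psfn_mod.PsfnSpec)
    dspn_spec: dspn_mod.DspnSpec = field(default_factory=dspn_mod.DspnSpec)
    head_hidden: int = 64
    variant: Variant = "base"
    epsilon: float = 0.2
    adasyn_k: int = 5
    adasyn_balance: float = 1.0
    training_regime: Regime = "pretrain_then_head"
    head_learning_rate: float = 1e-3
    head_epochs: int = 50
    head_patience: int = 5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.psfn_spec.num_classes != self.dspn_spec.num_classes:
            raise ValueError("branch specs disagree on the number of classes")

    @property
    def num_classes(self) -> int:
        return self.psfn_spec.num_classes


class HmpiModel:
    """Both branches plus the fusion head."""

    def __init__(self, spec: HmpiSpec, length: int) -> None:
        self.spec = spec
        self.length = length
        self.psfn = psfn_mod.build_psfn(spec.psfn_spec, length)
        self.dspn = dspn_mod.build_dspn(spec.dspn_spec, 12 * (length - 1))
        # at-variant heads consume the transferred (pooled block-2) features
        self.feature_mode: Literal["full", "transfer"] = (
            "transfer" if spec.variant == "at" else "full"
        )
        rng = np.random.default_rng(spec.seed + 1)
        self.head = nn.Sequential([
            nn.Dense(self.fused_dim, spec.head_hidden, rng, name="hmpi.head.hidden"),
            nn.ReLU(),
            nn.Dense(spec.head_hidden, spec.num_classes, rng, name="hmpi.head.out"),
        ])
        self.trained = False

    @property
    def fused_dim(self) -> int:
        psfn_dim = (
            self.spec.psfn_spec.feature_dim
            if self.feature_mode == "full"
            else self.spec.psfn_spec.block_filters[1]
        )
        return psfn_dim + self.spec.dspn_spec.block_sizes[-1]

    def fuse_features(self, onehot: np.ndarray, sp_flat: np.ndarray) -> np.ndarray:
        """Concatenated per-sample branch features (evaluation mode)."""
        layer = "feature_layer" if self.feature_mode == "full" else "second_block"
        seq_feats = psfn_mod.extract_features(self.psfn, onehot, layer=layer)
        struct_feats = dspn_mod.extract_structural_features(self.dspn, sp_flat)
        return np.concatenate([seq_feats, struct_feats], axis=1)


def build_hmpi(spec: HmpiSpec, length: int) -> HmpiModel:
    """Construct the hybrid for windows of the given length."""
    return HmpiModel(spec, length)


def predict(model: HmpiModel, onehot: np.ndarray, sp_flat: np.ndarray) -> np.ndarray:
    """Class probabilities, one row per sample (evaluation mode)."""
    fused = model.fuse_features(onehot, sp_flat)
    logits = model.head.forward(fused, train=False)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _train_head(
    model: HmpiModel,
    feats: np.ndarray,
    y: np.ndarray,
    feats_val: np.ndarray | None,
    y_val: np.ndarray | None,
    epsilon: float,
) -> list[dict]:
    """Adam on the (possibly label-smoothed) CCE over fixed fused features."""
    spec = model.spec
    rng = np.random.default_rng(spec.seed + 2)
    opt = nn.Adam(model.head.parameters(), lr=spec.head_learning_rate)
    n = feats.shape[0]
    y = np.asarray(y, dtype=int)
    log: list[dict] = []
    best_val, best_state, patience_left = np.inf, None, spec.head_patience
    for epoch in range(spec.head_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            opt.zero_grad()
            logits = model.head.forward(feats[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy_grad(logits, y[idx], epsilon=epsilon)
            model.head.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        entry = {"epoch": epoch + 1, "head_loss": epoch_loss / n}
        if feats_val is not None:
            logits = model.head.forward(feats_val, train=False)
            vloss, _ = nn.softmax_cross_entropy_grad(
                logits, np.asarray(y_val, dtype=int), epsilon=epsilon
            )
            entry["val_loss"] = vloss
            entry["val_acc"] = float(
                (logits.argmax(axis=1) == np.asarray(y_val)).mean()
            )
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = [p.value.copy() for p in model.head.parameters()]
                patience_left = spec.head_patience
            else:
                patience_left -= 1
        log.append(entry)
        if feats_val is not None and patience_left <= 0:
            break
    if best_state is not None:
        for p, v in zip(model.head.parameters(), best_state):
            p.value = v
    return log


def train_hmpi(
    model: HmpiModel,
    onehot_train: np.ndarray,
    sp_train: np.ndarray,
    y_train: np.ndarray,
    onehot_val: np.ndarray | None = None,
    sp_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Train the hybrid under the spec's regime; returns a structured log.

    ``pretrain_then_head`` trains the PSFN on its joint loss and the DSPN on
    CCE, freezes both, and fits the fusion head on the concatenated features
    (CCE, or label-smoothed CCE for the ``lsr`` variant). ``joint`` trains
    everything end to end on the summed objective.
    """
    spec = model.spec
    epsilon = spec.epsilon if spec.variant == "lsr" else 0.0
    log: dict = {"regime": spec.training_regime, "variant": spec.variant}
    if spec.training_regime == "pretrain_then_head":
        log["psfn"] = psfn_mod.train_psfn(
            model.psfn, onehot_train, y_train, onehot_val, y_val
        )
        log["dspn"] = dspn_mod.train_dspn(
            model.dspn, sp_train, y_train, sp_val, y_val
        )
        feats = model.fuse_features(onehot_train, sp_train)
        feats_val = (
            model.fuse_features(onehot_val, sp_val) if onehot_val is not None else None
        )
        log["head"] = _train_head(model, feats, y_train, feats_val, y_val, epsilon)
    elif spec.training_regime == "joint":
        log["joint"] = _train_joint(
            model, onehot_train, sp_train, y_train, onehot_val, sp_val, y_val, epsilon
        )
    else:
        raise ValueError(f"unknown training regime {spec.training_regime!r}")
    model.trained = True
    return log


def _train_joint(
    model: HmpiModel,
    onehot: np.ndarray,
    sp: np.ndarray,
    y: np.ndarray,
    onehot_val: np.ndarray | None,
    sp_val: np.ndarray | None,
    y_val: np.ndarray | None,
    epsilon: float,
) -> list[dict]:
    """End-to-end training: head loss backpropagated through both branches,
    plus the PSFN centre-loss term on its feature layer."""
    spec = model.spec
    pspec = spec.psfn_spec
    rng = np.random.default_rng(spec.seed)
    for blk in model.psfn.blocks:
        blk.seed_dropout(rng)
    model.psfn.feature.seed_dropout(rng)
    for blk in model.dspn.blocks:
        blk.seed_dropout(rng)
    params = [
        p
        for p in model.psfn.parameters() + model.dspn.parameters() + model.head.parameters()
        if p is not model.psfn.centres
    ]
    opt = nn.Adam(params, lr=spec.head_learning_rate)
    opt_centres = nn.Adam([model.psfn.centres], lr=pspec.centre_learning_rate)
    n = onehot.shape[0]
    y = np.asarray(y, dtype=int)
    split = pspec.feature_dim
    log: list[dict] = []
    for epoch in range(spec.head_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            yb = y[idx]
            opt.zero_grad()
            opt_centres.zero_grad()
            seq_feats = model.psfn.forward_features(onehot[idx], train=True)
            struct_feats = model.dspn.forward_features(sp[idx], train=True)
            fused = np.concatenate([seq_feats, struct_feats], axis=1)
            logits = model.head.forward(fused, train=True)
            loss, dlogits = nn.softmax_cross_entropy_grad(logits, yb, epsilon=epsilon)
            dfused = model.head.backward(dlogits)
            dseq, dstruct = dfused[:, :split], dfused[:, split:]
            if pspec.lambda_centre > 0:
                diff = seq_feats - model.psfn.centres.value[yb]
                loss += pspec.lambda_centre * float((diff**2).sum()) / len(yb)
                dseq = dseq + 2.0 * pspec.lambda_centre * diff / len(yb)
                np.add.at(
                    model.psfn.centres.grad, yb,
                    -2.0 * pspec.lambda_centre * diff / len(yb),
                )
            if not np.isfinite(loss):
                raise FloatingPointError(f"joint training diverged at epoch {epoch + 1}")
            model.psfn.backward_from_features(dseq)
            model.dspn.backward_from_features(dstruct)
            opt.step()
            if pspec.lambda_centre > 0:
                opt_centres.step()
            epoch_loss += loss * len(yb)
        entry = {"epoch": epoch + 1, "train_loss": epoch_loss / n}
        if onehot_val is not None:
            probs = predict(model, onehot_val, sp_val)
            entry["val_acc"] = float(
                (probs.argmax(axis=1) == np.asarray(y_val)).mean()
            )
        log.append(entry)
    return log


def run_hmpiat(
    model: HmpiModel,
    onehot_train: np.ndarray,
    sp_train: np.ndarray,
    y_train: np.ndarray,
    onehot_val: np.ndarray | None = None,
    sp_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """The ADASYN + transfer variant for imbalanced subtype data.

    Pretrains both branches on the imbalanced data, extracts the transferred
    feature space (pooled PSFN block-2 output concatenated with DSPN
    structural features), balances every minority class with ADASYN there,
    and trains the fusion head on the augmented feature set. Synthetic rows
    are counted in the returned log.
    """
    spec = model.spec
    model.feature_mode = "transfer"
    log: dict = {"regime": "adasyn_transfer", "variant": "at"}
    log["psfn"] = psfn_mod.train_psfn(
        model.psfn, onehot_train, y_train, onehot_val, y_val
    )
    log["dspn"] = dspn_mod.train_dspn(model.dspn, sp_train, y_train, sp_val, y_val)
    feats = model.fuse_features(onehot_train, sp_train)
    feats_aug, y_aug, synth_flag = imbalance.adasyn_per_class(
        feats, np.asarray(y_train, dtype=int),
        k=spec.adasyn_k, balance_level=spec.adasyn_balance, seed=spec.seed,
    )
    log["n_synthetic"] = int(synth_flag.sum())
    log["class_counts_after"] = {
        int(c): int(n) for c, n in zip(*np.unique(y_aug, return_counts=True))
    }
    feats_val = (
        model.fuse_features(onehot_val, sp_val) if onehot_val is not None else None
    )
    log["head"] = _train_head(model, feats_aug, y_aug, feats_val, y_val, epsilon=0.0)
    model.trained = True
    return log
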