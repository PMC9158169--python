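"""PSFN — the promoter sequence features network.

A three-block 1-D CNN over the 4 x L one-hot matrix. Each block is
convolution -> LeakyReLU(alpha=0.2) -> Dropout(0.25); the blocks carry
32, 64 and 128 feature maps with kernel sizes 3, 4 and 5, capturing
fine-, medium- and coarse-grained local sequence features respectively.
The last block is flattened into a ReLU dense layer that emits the sequence
feature vector, followed by a K-way softmax head.

Training uses the joint objective: categorical cross-entropy plus
``lambda * ||x - c_y||^2``, where the class centres ``c_y`` live in an
embedding updated by gradient alongside the network, giving intraclass
compactness on top of softmax separation. With ``lambda = 0`` this is the
plain-CCE variant (PSFNcce): same architecture, different loss only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import nn

FeatureLayer = Literal["feature_layer", "second_block"]


@dataclass
class PsfnSpec:
    """Architecture and training hyperparameters of the sequence branch."""

    block_filters: tuple[int, int, int] = (32, 64, 128)
    block_kernels: tuple[int, int, int] = (3, 4, 5)
    leaky_alpha: float = 0.2
    dropout_rate: float = 0.25
    feature_dim: int = 128
    num_classes: int = 2
    lambda_centre: float = 0.01
    #: the centre embedding gets its own, faster Adam rate so the centres can
    #: track the feature-space class means within a run
    centre_learning_rate: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_filters) != 3 or len(self.block_kernels) != 3:
            raise ValueError("the PSFN has exactly three convolution blocks")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.lambda_centre < 0:
            raise ValueError("lambda_centre must be >= 0")


class PsfnModel:
    """The assembled network plus its class-centre embedding."""

    def __init__(self, spec: PsfnSpec, length: int) -> None:
        min_l = max(spec.block_kernels)
        if length < min_l:
            raise ValueError(f"sequence length {length} too short; minimum is {min_l}")
        self.spec = spec
        self.length = length
        rng = np.random.default_rng(spec.seed)
        self.blocks: list[nn.Sequential] = []
        in_ch = 4
        for i, (f, k) in enumerate(zip(spec.block_filters, spec.block_kernels)):
            self.blocks.append(
                nn.Sequential([
                    nn.Conv1d(in_ch, f, k, rng, name=f"psfn.block{i + 1}.conv"),
                    nn.LeakyReLU(spec.leaky_alpha),
                    nn.Dropout(spec.dropout_rate),
                ])
            )
            in_ch = f
        self.feature = nn.Sequential([
            nn.Flatten(),
            nn.Dense(in_ch * length, spec.feature_dim, rng, name="psfn.feature"),
            nn.ReLU(),
        ])
        self.head = nn.Dense(spec.feature_dim, spec.num_classes, rng, name="psfn.head")
        self.centres = nn.Parameter(
            rng.normal(0.0, 0.1, size=(spec.num_classes, spec.feature_dim)),
            "psfn.centres",
        )
        self._block_outputs: list[np.ndarray] = []

    # -- forward / backward -------------------------------------------------

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """One-hot batch (n, 4, L) -> feature matrix (n, feature_dim)."""
        if x.ndim != 3 or x.shape[1] != 4 or x.shape[2] != self.length:
            raise ValueError(f"expected input of shape (n, 4, {self.length}), got {x.shape}")
        self._block_outputs = []
        h = x
        for blk in self.blocks:
            h = blk.forward(h, train)
            self._block_outputs.append(h)
        return self.feature.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.forward_features(x, train), train)

    def backward_from_features(self, dfeat: np.ndarray) -> np.ndarray:
        grad = self.feature.backward(dfeat)
        for blk in reversed(self.blocks):
            grad = blk.backward(grad)
        return grad

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.backward_from_features(self.head.backward(dlogits))

    # -- bookkeeping --------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        params = [p for blk in self.blocks for p in blk.parameters()]
        params += self.feature.parameters() + self.head.parameters()
        params.append(self.centres)
        return params

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value = v.copy()


def build_psfn(spec: PsfnSpec, length: int) -> PsfnModel:
    """Construct the sequence branch for windows of the given length."""
    return PsfnModel(spec, length)


def predict_proba(model: PsfnModel, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode class probabilities, one row per sample."""
    logits = model.forward(x, train=False)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def extract_features(
    model: PsfnModel, x: np.ndarray, layer: FeatureLayer = "feature_layer"
) -> np.ndarray:
    """Per-sample activations of the requested layer (evaluation mode).

    ``feature_layer`` is the final dense feature vector; ``second_block`` is
    the block-2 convolutional output reduced by global average pooling over
    positions to a fixed-length vector — the representation transferred to
    the resampling stage, where one-hot inputs themselves would be unusable.
    """
    feats = model.forward_features(x, train=False)
    if layer == "feature_layer":
        return feats
    if layer == "second_block":
        return model._block_outputs[1].mean(axis=2)
    raise ValueError(f"unknown layer tag {layer!r}")


def train_psfn(
    model: PsfnModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> list[dict]:
    """Adam on the joint CCE + centre loss; returns the per-epoch log.

    Early-stops on validation loss with the spec's patience and restores the
    best parameters. Fully reproducible for a fixed seed and thread count.
    """
    spec = model.spec
    y_train = np.asarray(y_train, dtype=int)
    if y_train.min() < 0 or y_train.max() >= spec.num_classes:
        raise ValueError("labels must lie in 0..K-1")
    rng = np.random.default_rng(spec.seed)
    for blk in model.blocks:
        blk.seed_dropout(rng)
    model.feature.seed_dropout(rng)
    net_params = [p for p in model.parameters() if p is not model.centres]
    opt = nn.Adam(net_params, lr=spec.learning_rate)
    opt_centres = nn.Adam([model.centres], lr=spec.centre_learning_rate)

    n = x_train.shape[0]
    log: list[dict] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    patience_left = spec.patience

    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            opt.zero_grad()
            opt_centres.zero_grad()
            feats = model.forward_features(xb, train=True)
            logits = model.head.forward(feats, train=True)
            loss, dlogits = nn.softmax_cross_entropy_grad(logits, yb)
            dfeat = model.head.backward(dlogits)
            if spec.lambda_centre > 0:
                diff = feats - model.centres.value[yb]
                loss += spec.lambda_centre * float((diff**2).sum()) / len(yb)
                dfeat = dfeat + 2.0 * spec.lambda_centre * diff / len(yb)
                np.add.at(
                    model.centres.grad, yb, -2.0 * spec.lambda_centre * diff / len(yb)
                )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch + 1}: loss={loss}"
                )
            model.backward_from_features(dfeat)
            opt.step()
            if spec.lambda_centre > 0:
                opt_centres.step()
            epoch_loss += loss * len(yb)
        entry = {"epoch": epoch + 1, "train_loss": epoch_loss / n}

        if x_val is not None:
            probs = predict_proba(model, x_val)
            val_y = np.asarray(y_val, dtype=int)
            logp = np.log(np.maximum(probs[np.arange(len(val_y)), val_y], 1e-12))
            entry["val_loss"] = float(-logp.mean())
            entry["val_acc"] = float((probs.argmax(axis=1) == val_y).mean())
            if entry["val_loss"] < best_val - 1e-6:
                best_val = entry["val_loss"]
                best_state = model.get_state()
                patience_left = spec.patience
            else:
                patience_left -= 1
        log.append(entry)
        if x_val is not None and patience_left <= 0:
            break
    if best_state is not None:
        model.set_state(best_state)
    return log
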