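"""DSPN — the deep structural profiles network.

Seven fully connected blocks over the flattened 12 x (L-1) structural-profile
matrix, with dense-style skip concatenations: the raw SP input is concatenated
into the inputs of blocks 3 and 6, and the block-2 output is additionally
concatenated into block 6. Each block is
Dense -> LeakyReLU -> Dropout(0.2) -> BatchNorm, in that order. The block-7
output (128 units) is the structural feature vector; a K-way softmax head
trained with plain categorical cross-entropy sits on top.

The direct links give the gradient short routes from the loss to the raw
structural profiles, encouraging feature reuse and easing training of the
deep stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn

#: Block widths for 251-bp eukaryotic windows (input 12 x 250).
EUKARYOTIC_BLOCKS = (250, 1000, 250, 1000, 1500, 1000, 128)
#: Block widths for 81-bp prokaryotic windows (input 12 x 80).
PROKARYOTIC_BLOCKS = (80, 500, 80, 150, 500, 500, 128)


@dataclass
class DspnSpec:
    """Architecture and training hyperparameters of the structural branch."""

    block_sizes: tuple[int, ...] = EUKARYOTIC_BLOCKS
    leaky_alpha: float = 0.2
    dropout_rate: float = 0.2
    num_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    patience: int = 5
    seed: int = 0
    # blocks receiving the raw SP input concatenated, and the block whose
    # output is re-linked into block 6 (1-based indices, fixed topology)
    skip_inputs_to: tuple[int, int] = (3, 6)
    skip_block2_to: int = 6

    def __post_init__(self) -> None:
        if len(self.block_sizes) != 7:
            raise ValueError("the DSPN has exactly seven blocks")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")

    @classmethod
    def eukaryotic(cls, **kw) -> "DspnSpec":
        return cls(block_sizes=EUKARYOTIC_BLOCKS, **kw)

    @classmethod
    def prokaryotic(cls, **kw) -> "DspnSpec":
        return cls(block_sizes=PROKARYOTIC_BLOCKS, **kw)


def _block(n_in: int, n_out: int, spec: DspnSpec, rng: np.random.Generator,
           name: str) -> nn.Sequential:
    # Composition order is Dense -> LeakyReLU -> Dropout -> BatchNorm.
    return nn.Sequential([
        nn.Dense(n_in, n_out, rng, name=f"{name}.dense"),
        nn.LeakyReLU(spec.leaky_alpha),
        nn.Dropout(spec.dropout_rate),
        nn.BatchNorm(n_out, name=f"{name}.bn"),
    ])


class DspnModel:
    """The assembled seven-block network with its skip concatenations."""

    def __init__(self, spec: DspnSpec, input_dim: int) -> None:
        self.spec = spec
        self.input_dim = input_dim
        s = spec.block_sizes
        rng = np.random.default_rng(spec.seed)
        widths = [
            input_dim,               # block 1
            s[0],                    # block 2
            s[1] + input_dim,        # block 3: block-2 output + SP input
            s[2],                    # block 4
            s[3],                    # block 5
            s[4] + input_dim + s[1], # block 6: block-5 + SP input + block-2
            s[5],                    # block 7
        ]
        self.blocks = [
            _block(widths[i], s[i], spec, rng, name=f"dspn.block{i + 1}")
            for i in range(7)
        ]
        self.head = nn.Dense(s[6], spec.num_classes, rng, name="dspn.head")
        self._h2: np.ndarray | None = None
        self._h7: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def block_input_widths(self) -> list[int]:
        """Actual input width of each block (skip bookkeeping made explicit)."""
        return [blk.layers[0].n_in for blk in self.blocks]

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Flattened SP batch (n, 12*(L-1)) -> structural features (n, 128)."""
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ValueError(
                f"expected input of shape (n, {self.input_dim}) "
                f"(= 12 * (L - 1) flattened), got {x.shape}"
            )
        self._x = x
        h1 = self.blocks[0].forward(x, train)
        h2 = self.blocks[1].forward(h1, train)
        self._h2 = h2
        h3 = self.blocks[2].forward(np.concatenate([h2, x], axis=1), train)
        h4 = self.blocks[3].forward(h3, train)
        h5 = self.blocks[4].forward(h4, train)
        h6 = self.blocks[5].forward(np.concatenate([h5, x, h2], axis=1), train)
        h7 = self.blocks[6].forward(h6, train)
        self._h7 = h7
        return h7

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.forward_features(x, train), train)

    def backward_from_features(self, dh7: np.ndarray) -> np.ndarray:
        """Backpropagate to the SP input, summing all three gradient routes."""
        s = self.spec.block_sizes
        d = self.input_dim
        dh6 = self.blocks[6].backward(dh7)
        dcat6 = self.blocks[5].backward(dh6)
        dh5, dx_skip6, dh2_skip = (
            dcat6[:, : s[4]],
            dcat6[:, s[4] : s[4] + d],
            dcat6[:, s[4] + d :],
        )
        dh4 = self.blocks[4].backward(dh5)
        dh3 = self.blocks[3].backward(dh4)
        dcat3 = self.blocks[2].backward(dh3)
        dh2 = dcat3[:, : s[1]] + dh2_skip
        dx_skip3 = dcat3[:, s[1] :]
        dh1 = self.blocks[1].backward(dh2)
        dx_main = self.blocks[0].backward(dh1)
        return dx_main + dx_skip3 + dx_skip6

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.backward_from_features(self.head.backward(dlogits))

    def parameters(self) -> list[nn.Parameter]:
        params = [p for blk in self.blocks for p in blk.parameters()]
        return params + self.head.parameters()

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.parameters()]
        for blk in self.blocks:
            bn = blk.layers[3]
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.parameters())
        for p, v in zip(self.parameters(), state[:n]):
            p.value = v.copy()
        rest = state[n:]
        for i, blk in enumerate(self.blocks):
            bn = blk.layers[3]
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()


def build_dspn(spec: DspnSpec, input_dim: int) -> DspnModel:
    """Construct the structural branch for a flattened 12*(L-1) input."""
    return DspnModel(spec, input_dim)


def predict_proba(model: DspnModel, x: np.ndarray) -> np.ndarray:
    logits = model.forward(x, train=False)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def extract_structural_features(model: DspnModel, x: np.ndarray) -> np.ndarray:
    """Block-7 activations (n x 128), evaluation mode."""
    return model.forward_features(x, train=False)


def flatten_sp(sp: np.ndarray) -> np.ndarray:
    """Flatten (n, 12, L-1) SP matrices row-major (property-major)."""
    return sp.reshape(sp.shape[0], -1)


def train_dspn(
    model: DspnModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> list[dict]:
    """Adam on plain CCE; early-stops on validation loss; returns the log."""
    spec = model.spec
    y_train = np.asarray(y_train, dtype=int)
    if y_train.min() < 0 or y_train.max() >= spec.num_classes:
        raise ValueError("labels must lie in 0..K-1")
    rng = np.random.default_rng(spec.seed)
    for blk in model.blocks:
        blk.seed_dropout(rng)
    opt = nn.Adam(model.parameters(), lr=spec.learning_rate)

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
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy_grad(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch + 1}: loss={loss}"
                )
            model.backward(dlogits)
            opt.step()
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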