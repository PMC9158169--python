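"""A compact numpy backprop engine for the promoter models.

Implements exactly the layer vocabulary the models need — 1-D convolution
(same padding, stride 1), dense layers, LeakyReLU/ReLU, inverted dropout,
batch normalization — plus Adam. Layers cache what their backward pass needs;
``Sequential`` chains them. Shapes follow the (batch, channels, length)
convention for convolutions and (batch, features) for dense layers.

Determinism: all randomness (init, dropout masks, shuffling) flows from
numpy Generators seeded explicitly by the callers, so a fixed seed and fixed
thread count reproduce runs bit-for-bit.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base layer: forward caches, backward consumes the cache."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense") -> None:
        self.n_in, self.n_out = n_in, n_out
        self.W = Parameter(he_init(rng, (n_in, n_out), n_in), f"{name}.W")
        self.b = Parameter(np.zeros(n_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected input width {self.n_in}, got {x.shape[1]}")
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class Conv1d(Layer):
    """1-D convolution over (batch, channels, length), stride 1, same padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        name: str = "conv",
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        # weight layout (C*k, F): column-major over taps within a channel block
        self.W = Parameter(he_init(rng, (fan_in, out_channels), fan_in), f"{name}.W")
        self.b = Parameter(np.zeros(out_channels), f"{name}.b")
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _pad(self) -> tuple[int, int]:
        left = (self.kernel_size - 1) // 2
        return left, self.kernel_size - 1 - left

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        if length < self.kernel_size:
            raise ValueError(
                f"sequence length {length} shorter than kernel {self.kernel_size}"
            )
        self._in_shape = x.shape
        pl, pr = self._pad()
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # windows: (B, C, L, k) -> (B, L, C*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel_size, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(b * length, c * self.kernel_size)
        self._cols = cols
        out = cols @ self.W.value + self.b.value
        return out.reshape(b, length, self.out_channels).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, length = self._in_shape
        k = self.kernel_size
        g = grad.transpose(0, 2, 1).reshape(b * length, self.out_channels)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value.T).reshape(b, length, c, k).transpose(0, 2, 1, 3)
        pl, pr = self._pad()
        dxp = np.zeros((b, c, length + pl + pr))
        for t in range(k):
            dxp[:, :, t : t + length] += dcols[:, :, :, t]
        return dxp[:, :, pl : pl + length]

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Dropout(Layer):
    """Inverted dropout: active only in training; identity at evaluation."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Batch normalization over the batch axis of (batch, features) inputs."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(n_features), f"{name}.gamma")
        self.beta = Parameter(np.zeros(n_features), f"{name}.beta")
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        self._cache = (xhat, inv_sd, train, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_sd, train, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not train:
            return g * inv_sd
        return (inv_sd / n) * (n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def seed_dropout(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng.integers(2**31))
            elif isinstance(layer, Sequential):
                layer.seed_dropout(rng)


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax_cross_entropy_grad(
    logits: np.ndarray, y: np.ndarray, epsilon: float = 0.0
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy (optionally label-smoothed) and its logit gradient.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss, i.e. ``(softmax(z) - q) / batch``.
    """
    n, k = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    p = np.exp(logp)
    q = np.full_like(p, epsilon / k)
    q[np.arange(n), y] += 1.0 - epsilon
    loss = float(-(q * logp).sum() / n)
    return loss, (p - q) / n
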