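"""A small, deterministic NumPy neural-network engine.

Implements exactly the pieces the 1-D convolutional classifiers need:
valid (no-padding, stride-1) 1-D convolution, non-overlapping max
pooling, inverted dropout parameterised by keep-probability, dense
layers, ReLU, a fused softmax/cross-entropy head, Xavier-normal
initialisation, and Adam/SGD optimisers. Forward passes cache what the
analytic backward passes need; gradients are verified against finite
differences in the test suite.

Tensors are ``(batch, length, channels)`` for convolutional stages and
``(batch, features)`` after flattening. All randomness (init, dropout)
flows through explicitly passed ``numpy.random.Generator`` objects, so a
single seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigError

__all__ = [
    "xavier_normal",
    "Layer",
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "SGD",
]


def xavier_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    """Glorot/Xavier normal init: N(0, 2 / (fan_in + fan_out))."""
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


class Layer:
    """Base layer: forward caches, backward returns input gradient."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1.

    Weights ``W`` have shape (kernel, in_channels, filters); input
    (B, L, Cin) maps to (B, L - K + 1, F).
    """

    def __init__(self, kernel_size: int, in_channels: int, n_filters: int,
                 rng: np.random.Generator, init: str = "xavier_normal"):
        if kernel_size < 1 or n_filters < 1:
            raise ConfigError("kernel_size and n_filters must be >= 1")
        self.kernel_size = kernel_size
        shape = (kernel_size, in_channels, n_filters)
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * n_filters
        if init == "xavier_normal":
            self.W = xavier_normal(rng, shape, fan_in, fan_out)
        else:  # uniform He-style fallback ("default")
            bound = np.sqrt(1.0 / fan_in)
            self.W = rng.uniform(-bound, bound, size=shape)
        self.b = np.zeros(n_filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train, rng):
        K = self.kernel_size
        if x.shape[1] < K:
            raise ConfigError(f"kernel_size {K} exceeds input length {x.shape[1]}")
        self._x = x
        # windows: (B, Lout, Cin, K)
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)
        return np.einsum("blck,kcf->blf", win, self.W, optimize=True) + self.b

    def backward(self, grad):
        x = self._x
        K = self.kernel_size
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)
        self.dW[...] = np.einsum("blck,blf->kcf", win, grad, optimize=True)
        self.db[...] = grad.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        Lout = grad.shape[1]
        for k in range(K):
            # position i of the output touches input position i + k
            dx[:, k:k + Lout, :] += np.einsum("blf,cf->blc", grad, self.W[k], optimize=True)
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling (stride = window); remainder dropped.

    Window 1 is the identity — the architecture search can turn pooling
    off per branch.
    """

    def __init__(self, window: int):
        if window < 1:
            raise ConfigError("pool window must be >= 1")
        self.window = window

    def forward(self, x, train, rng):
        w = self.window
        if w == 1:
            self._shape = None
            return x
        B, L, C = x.shape
        Lp = L // w
        if Lp == 0:
            raise ConfigError(f"pool window {w} exceeds input length {L}")
        xt = x[:, : Lp * w, :].reshape(B, Lp, w, C)
        self._argmax = xt.argmax(axis=2)
        self._shape = (B, L, C, Lp, w)
        return np.take_along_axis(xt, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        if self._shape is None:
            return grad
        B, L, C, Lp, w = self._shape
        dxt = np.zeros((B, Lp, w, C))
        np.put_along_axis(dxt, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, : Lp * w, :] = dxt.reshape(B, Lp * w, C)
        return dx


class Dropout(Layer):
    """Inverted dropout parameterised by keep-probability.

    At train time each unit is kept with probability ``keep_prob`` and
    scaled by 1/keep_prob; evaluation is the identity.
    """

    def __init__(self, keep_prob: float):
        if not (0.0 < keep_prob <= 1.0):
            raise ConfigError(f"keep_prob must be in (0, 1], got {keep_prob}")
        self.keep_prob = keep_prob

    def forward(self, x, train, rng):
        if not train or self.keep_prob >= 1.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) < self.keep_prob) / self.keep_prob
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "xavier_normal"):
        if init == "xavier_normal":
            self.W = xavier_normal(rng, (n_in, n_out), n_in, n_out)
        else:
            bound = np.sqrt(1.0 / n_in)
            self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                out[f"{prefix}{i}.{name}"] = arr
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.grads().items():
                out[f"{prefix}{i}.{name}"] = arr
        return out


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


# ---------------------------------------------------------------------------
# Optimisers
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p -= self.lr * grads[k]
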