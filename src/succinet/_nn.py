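"""Minimal deterministic neural-network kernel (NumPy).

Implements exactly the layers the site-prediction architectures need:
token embedding, length-preserving 1-D convolution, max pooling
(strided and stride-1 "same"), dense, ReLU, dropout and sigmoid, plus
the Adam optimizer and binary cross-entropy. All randomness (weight
init, shuffling, dropout) flows through explicit ``numpy`` generators,
so training is bit-reproducible on a fixed seed and single thread.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


class Layer:
    """Base layer: parameters in ``params``, matching grads in ``grads``."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Embedding(Layer):
    """Learned token-embedding lookup: (N, L) ints -> (N, L, d)."""

    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.params["E"] = rng.uniform(-0.05, 0.05, size=(vocab, dim))

    def forward(self, x, train=False):
        self._tokens = x
        return self.params["E"][x]

    def backward(self, dout):
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, self._tokens, dout)
        self.grads["E"] = dE
        return None  # tokens are not differentiable


class Conv1D(Layer):
    """Length-preserving ("same", zero-padded) 1-D convolution.

    Input (N, L, C_in) -> output (N, L, F). Kernel size must be odd.
    """

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.c_in = c_in
        self.filters = filters
        fan_in = kernel * c_in
        self.params["W"] = glorot_uniform(rng, fan_in, filters, (kernel * c_in, filters))
        self.params["b"] = np.zeros(filters)

    def forward(self, x, train=False):
        n, length, c = x.shape
        p = (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # (N, L, kernel, C) -> (N*L, kernel*C)
        cols = sliding_window_view(xp, self.kernel, axis=1)  # (N, L, C, k)
        cols = cols.transpose(0, 1, 3, 2).reshape(n * length, self.kernel * c)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, length, self.filters)

    def backward(self, dout):
        n, length, c = self._in_shape
        d2 = dout.reshape(n * length, self.filters)
        self.grads["W"] = self._cols.T @ d2
        self.grads["b"] = d2.sum(axis=0)
        dcols = (d2 @ self.params["W"].T).reshape(n, length, self.kernel, c)
        p = (self.kernel - 1) // 2
        dxp = np.zeros((n, length + 2 * p, c))
        for j in range(self.kernel):
            dxp[:, j : j + length] += dcols[:, :, j]
        return dxp[:, p : p + length]


class MaxPool1D(Layer):
    """Strided max pool with floor length division: (N, L, C) -> (N, L//p, C)."""

    trainable = False

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        n, length, c = x.shape
        m = length // self.pool
        xt = x[:, : m * self.pool].reshape(n, m, self.pool, c)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, dout):
        n, length, c = self._in_shape
        m = length // self.pool
        dxt = np.zeros((n, m, self.pool, c))
        np.put_along_axis(dxt, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((n, length, c))
        dx[:, : m * self.pool] = dxt.reshape(n, m * self.pool, c)
        return dx


class MaxPool1DSame(Layer):
    """Stride-1 max pool with same padding (used in the inception pool branch)."""

    trainable = False

    def __init__(self, kernel: int = 3):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel

    def forward(self, x, train=False):
        n, length, c = x.shape
        p = (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, self.kernel, axis=1)  # (N, L, C, k)
        self._argmax = win.argmax(axis=3)
        self._in_shape = x.shape
        return win.max(axis=3)

    def backward(self, dout):
        n, length, c = self._in_shape
        p = (self.kernel - 1) // 2
        dxp = np.zeros((n, length + 2 * p, c))
        # argmax index j within window at position t maps to padded index t + j
        t_idx = np.arange(length)[None, :, None]
        src = t_idx + self._argmax  # (N, L, C)
        n_idx = np.arange(n)[:, None, None]
        c_idx = np.arange(c)[None, None, :]
        np.add.at(dxp, (n_idx, src, c_idx), dout)
        return dxp[:, p : p + length]


class ReLU(Layer):
    trainable = False

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    trainable = False

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, d_in, d_out, (d_in, d_out))
        self.params["b"] = np.zeros(d_out)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    trainable = False

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sigmoid(Layer):
    trainable = False

    def forward(self, x, train=False):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


def run_forward(layers, x, train=False):
    for layer in layers:
        x = layer.forward(x, train=train)
    return x


def run_backward(layers, dout):
    for layer in reversed(layers):
        dout = layer.backward(dout)
    return dout


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the probabilities.

    Probabilities are clipped to [1e-7, 1 - 1e-7] for numerical safety.
    """
    p = np.clip(probs, 1e-7, 1.0 - 1e-7)
    y = labels.astype(float)
    n = len(y)
    loss = -float(np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    inside = (probs > 1e-7) & (probs < 1.0 - 1e-7)
    dp = np.where(inside, (p - y) / (p * (1.0 - p) * n), 0.0)
    return loss, dp


class Adam:
    """Adam over the trainable parameters of a list of layers."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.slots = [
            (layer, name)
            for layer in layers
            if layer.trainable
            for name in layer.params
        ]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
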