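"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Only what the latent binding model needs: 1-D convolution (valid padding),
ReLU, global max-pooling over positions, dense layers, and Adam. Layers cache
their forward inputs and accumulate parameter gradients in ``backward``;
``zero_grad`` clears them. All computation is float64 and deterministic for a
fixed seed (single-threaded NumPy ops only).
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Dense:
    """Affine map (B, n_in) -> (B, n_out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    @property
    def params(self):
        return [self.W, self.b]


class Conv1d:
    """Valid 1-D convolution over positions: (B, L, C_in) -> (B, L-K+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in = c_in
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, length, c = x.shape
        out_len = length - self.kernel + 1
        cols = np.empty((b, out_len, self.kernel * c))
        for k in range(self.kernel):
            cols[:, :, k * c:(k + 1) * c] = x[:, k:k + out_len, :]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, out_len, c_out = g.shape
        cols2d = self._cols.reshape(-1, self.W.value.shape[0])
        g2d = g.reshape(-1, c_out)
        self.W.grad += cols2d.T @ g2d
        self.b.grad += g2d.sum(axis=0)
        gcols = g @ self.W.value.T  # (B, out_len, K*C_in)
        gx = np.zeros(self._in_shape)
        c = self.c_in
        for k in range(self.kernel):
            gx[:, k:k + out_len, :] += gcols[:, :, k * c:(k + 1) * c]
        return gx

    @property
    def params(self):
        return [self.W, self.b]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)

    @property
    def params(self):
        return []


class GlobalMaxPool:
    """Max over the position axis: (B, L, C) -> (B, C)."""

    def __init__(self):
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        self._argmax = x.argmax(axis=1)
        return np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape)
        np.put_along_axis(gx, self._argmax[:, None, :], g[:, None, :], axis=1)
        return gx

    @property
    def params(self):
        return []


class Flatten:
    """(B, L, C) -> (B, L*C)."""

    def __init__(self):
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._in_shape)

    @property
    def params(self):
        return []


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out


def softplus(x: np.ndarray) -> np.ndarray:
    # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.weight_decay = 0.0  # decoupled (AdamW-style)
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
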