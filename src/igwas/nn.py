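"""A minimal feed-forward / convolutional network core on numpy.

Implements exactly what the package's two small models need: 3x3
same-padding convolutions, 2x2 average pooling, dense layers, ReLU,
softmax / sigmoid cross-entropy, and Adam — all with hand-derived
backward passes. Layout is NHWC throughout. Everything is deterministic
given the initializing Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "ReLU", "Conv3x3", "AvgPool2", "Flatten", "Sequential", "Adam",
    "softmax", "softmax_xent", "sigmoid", "binary_xent",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over integer targets; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.mean(np.log(p[np.arange(n), targets] + 1e-300))
    d = p.copy()
    d[np.arange(n), targets] -= 1.0
    return loss, d / n


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def binary_xent(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    p = sigmoid(logits)
    loss = -np.mean(targets * np.log(p + 1e-12) + (1 - targets) * np.log(1 - p + 1e-12))
    return loss, (p - targets) / logits.size


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding, NHWC."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.standard_normal((3, 3, c_in, c_out)) * scale
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        self._shape = (n, h, w)
        out = np.tile(self.b, (n, h, w, 1)).astype(float)
        for di in range(3):
            for dj in range(3):
                out += xp[:, di:di + h, dj:dj + w, :] @ self.W[di, dj]
        return out

    def backward(self, g):
        n, h, w = self._shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, di:di + h, dj:dj + w, :]
                self.grads[0][di, dj] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di:di + h, dj:dj + w, :] += g @ self.W[di, dj].T
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        return dxp[:, 1:-1, 1:-1, :]


class AvgPool2:
    """2x2 average pooling (input H, W must be even)."""

    params: list = []
    grads: list = []

    def forward(self, x):
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, g):
        n, h, w, c = self._shape
        g = g[:, :, None, :, None, :] / 4.0
        return np.broadcast_to(g, (n, h // 2, 2, w // 2, 2, c)).reshape(n, h, w, c)


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
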