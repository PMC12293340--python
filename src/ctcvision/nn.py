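"""Minimal CNN machinery: layers, backprop, SGD with momentum.

Arrays are float32, NCHW layout.  Convolutions are valid (no padding),
stride 1, implemented by im2col so the inner loop is a BLAS matmul.
Everything is seeded: weight initialization from the model seed, dropout
from a dedicated substream, so two identical runs produce identical
parameter trajectories.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "SGDMomentum",
    "softmax",
    "cross_entropy_grad",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    cols = np.empty((n, ho, wo, c, k, k), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[..., i, j] = x[:, :, i : i + ho, j : j + wo].transpose(0, 2, 3, 1)
    return cols.reshape(n, ho, wo, c * k * k)


class Conv2D:
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)  # (n, ho, wo, fan_in)
        y = self._cols @ self.w.T + self.b
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.transpose(0, 2, 3, 1)  # (n, ho, wo, out)
        n, ho, wo, _ = g.shape
        gf = g.reshape(-1, self.out_ch)
        cf = self._cols.reshape(-1, self.w.shape[1])
        self.dw[:] = gf.T @ cf
        self.db[:] = gf.sum(axis=0)
        dcols = (gf @ self.w).reshape(n, ho, wo, self.in_ch, self.k, self.k)
        dx = np.zeros(self._shape, dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + ho, j : j + wo] += dcols[..., i, j].transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; a trailing odd row/column is dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        self._shape = x.shape
        t = x[:, :, : 2 * ho, : 2 * wo].reshape(n, c, ho, 2, wo, 2)
        t = t.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._arg = t.argmax(axis=-1)
        return np.take_along_axis(t, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, ho, wo = grad.shape
        flat = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._shape, dtype=np.float32)
        dx[:, :, : 2 * ho, : 2 * wo] = flat.reshape(n, c, 2 * ho, 2 * wo)
        return dx

    def params(self):
        return []


class Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Dropout:
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask

    def params(self):
        return []


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGDMomentum:
    """Classic momentum: v <- m*v - lr*g; w <- w + v."""

    def __init__(self, layers, lr: float, momentum: float = 0.9):
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self._vel = [
            [np.zeros_like(p) for p, _ in layer.params()] for layer in layers
        ]

    def step(self) -> None:
        for layer, vels in zip(self.layers, self._vel):
            for (p, g), v in zip(layer.params(), vels):
                v *= self.momentum
                v -= self.lr * g
                p += v
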