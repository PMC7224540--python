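"""Layers for the numpy conv net.

All activations are float32 arrays in NHWC layout.  Each layer implements
``forward(x, train)`` and ``backward(grad)``; layers with weights expose
``params`` / ``grads`` lists consumed by the SGD update.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 same-padding convolution via im2col + GEMM.

    Kernel size is fixed at 3x3 by design (the backbone contract); He-normal
    initialization from the supplied generator.
    """

    kernel_size = (3, 3)

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # (n, h, w, c, 3, 3) -> (n*h*w, c*9); window axes ordered (dy, dx)
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, c * 9)
        self._cols = cols if train else None
        self._shape = (n, h, w, c)
        out = cols @ self.W + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, grad):
        n, h, w, c = self._shape
        g = grad.reshape(n * h * w, -1).astype(np.float32)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for dy in range(3):
            for dx in range(3):
                dxp[:, dy : dy + h, dx : dx + w, :] += dcols[:, :, :, dy, dx, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """Non-overlapping k x k max pooling (input sides must divide by k)."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k = self.k
        xr = x.reshape(n, h // k, k, w // k, k, c)
        out = xr.max(axis=(2, 4))
        self._x = x
        self._out = out
        return out

    def backward(self, grad):
        n, h, w, c = self._x.shape
        k = self.k
        up = np.repeat(np.repeat(self._out, k, axis=1), k, axis=2)
        mask = self._x == up
        gup = np.repeat(np.repeat(grad, k, axis=1), k, axis=2)
        return (gup * mask).astype(np.float32)


class AvgPool2D(Layer):
    """Non-overlapping k x k average pooling; used as a downsampling stem."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k = self.k
        self._shape = x.shape
        return x.reshape(n, h // k, k, w // k, k, c).mean(axis=(2, 4))

    def backward(self, grad):
        k = self.k
        g = np.repeat(np.repeat(grad, k, axis=1), k, axis=2) / (k * k)
        return g.astype(np.float32)


class GlobalAvgPool(Layer):
    """Spatial mean of each feature map; enables class activation mapping."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return (
            np.broadcast_to(grad[:, None, None, :], (n, h, w, c)) / (h * w)
        ).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout, active only in training; seeded via set_rng."""

    def __init__(self, rate: float):
        self.rate = rate
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator):
        self._rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
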