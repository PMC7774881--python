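"""Minimal CPU neural-network layers with explicit backpropagation.

Everything operates on float32 arrays in NCHW layout. Each layer exposes
``forward(x, train)`` and ``backward(dy)`` plus ``params()`` yielding
(name, value, gradient) triples; convolutions are evaluated as im2col
matrix products so the heavy lifting lands in BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "UpsampleNearest2",
]


class Layer:
    def params(self):
        return ()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k same-padding convolution (k in {1, 3})."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        yield "w", self.w, self.dw
        yield "b", self.b, self.db

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            return x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (n, c, h, w, 3, 3) -> rows over pixels, cols over (c, ki, kj)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * 9
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        if train:
            self._cols, self._xshape = cols, x.shape
        wmat = self.w.reshape(self.c_out, -1)
        y = cols @ wmat.T + self.b
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._xshape
        dyr = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dw[...] = (dyr.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dyr.sum(axis=0)
        dcols = dyr @ self.w.reshape(self.c_out, -1)
        if self.k == 1:
            return dcols.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(n, h, w, self.c_in, 3, 3)
        dx = np.zeros((n, self.c_in, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dx[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dx[:, :, 1 : 1 + h, 1 : 1 + w]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        yield "gamma", self.gamma, self.dgamma
        yield "beta", self.beta, self.dbeta

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._xhat, self._inv = xhat.astype(np.float32), inv.astype(np.float32)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[:, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[:, None, None]
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            mask = xr == y[:, :, :, None, :, None]
            # break pooling ties deterministically: keep first max only
            flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
            flat &= np.cumsum(flat, axis=-1) <= 1
            self._mask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5
            )
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dx = self._mask * dy[:, :, :, None, :, None]
        return dx.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
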