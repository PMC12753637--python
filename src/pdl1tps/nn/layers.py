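"""Minimal CPU layer library with explicit backpropagation.

All layers operate on float32 arrays in NCHW layout. Each layer caches what
its backward pass needs during ``forward`` and releases it after ``backward``.
Parameters are :class:`Param` objects so the optimizer and checkpointing can
enumerate them generically.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "GroupNorm",
    "ConvTranspose2d",
    "MaxPool2d",
    "ReLU",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """2-D convolution (cross-correlation) with 'same'-style zero padding.

    Padding defaults to k//2 so stride-1 convolutions preserve the spatial
    shape and stride-2 convolutions halve it exactly for even inputs.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        self.c_in, self.c_out = c_in, c_out
        # He initialisation for ReLU networks
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, std, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        wm = self.w.value.reshape(self.c_out, -1)
        y = cols @ wm.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        self._cache = None
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyr = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.w.grad += (dyr.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dyr.sum(axis=0)
        dcols = (dyr @ self.w.value.reshape(self.c_out, -1)).reshape(
            n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2d:
    """Transpose convolution with kernel == stride (non-overlapping upsampling)."""

    def __init__(self, c_in: int, c_out: int, k: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, std, size=(c_in, c_out, k, k)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        t = np.tensordot(x, self.w.value, axes=([1], [0]))  # n,h,w,co,k,k
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.c_out, h * k, w * k)
        y = y + self.b.value[None, :, None, None]
        self._cache = x
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        n, c, h, w = x.shape
        k = self.k
        dyt = dy.reshape(n, self.c_out, h, k, w, k).transpose(0, 2, 4, 1, 3, 5)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        self.w.grad += np.tensordot(x, dyt, axes=([0, 2, 3], [0, 1, 2]))
        dx = np.tensordot(dyt, self.w.value, axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class MaxPool2d:
    """2x2 max pooling, stride 2. Ties route the gradient to the first maximum."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        self._cache = None
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class GroupNorm:
    """Group normalisation with learnable scale and shift.

    Normalises over channel groups per sample, so the statistics do not
    depend on the batch size — appropriate for the small batches used here.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        while channels % groups:
            groups //= 2
        self.groups, self.eps = max(groups, 1), eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(n, c, h, w).astype(np.float32)
        self._cache = (xhat, inv.astype(np.float32), x.shape)
        return xhat * self.gamma.value[None, :, None, None] \
            + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, (n, c, h, w) = self._cache
        self._cache = None
        g = self.groups
        self.gamma.grad += np.einsum("nchw,nchw->c", dy, xhat)
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[None, :, None, None]).reshape(n, g, -1)
        xhat_g = xhat.reshape(n, g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xhat_g).mean(axis=2, keepdims=True)
        dx = (dxhat - m1 - xhat_g * m2) * inv
        return dx.reshape(n, c, h, w).astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, self._mask = self._mask, None
        return np.where(m, dy, 0.0).astype(np.float32)
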