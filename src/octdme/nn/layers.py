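"""Layers with explicit forward/backward passes.

Convolutions use an im2col formulation so the heavy lifting is a single
matrix product per layer. Each layer caches what its backward pass needs;
a layer must therefore see backward() for the forward() that preceded it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Dropout",
    "Flatten",
    "GlobalAveragePool",
    "GlobalMaxPool",
    "Dense",
]


class Layer:
    """Base class: stateless by default, no parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back onto the image."""
    n, c, h, w = shape
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2D(Layer):
    """Stride-1 'same' convolution with He-initialised weights."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.w = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        self._xshape = x.shape
        self._cols = _im2col(x, self.k, self.k // 2)
        out = np.matmul(self.w[None], self._cols) + self.b[None, :, None]
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, gy):
        n, _, h, w = gy.shape
        gyf = gy.reshape(n, self.out_ch, h * w)
        self.gw[...] = np.einsum("nof,ncf->oc", gyf, self._cols, optimize=True)
        self.gb[...] = gyf.sum(axis=(0, 2))
        gcols = np.matmul(self.w.T[None], gyf)
        self._cols = None
        return _col2im(gcols, self._xshape, self.k, self.k // 2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._inshape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        return g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x up-sampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class GlobalAveragePool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape).copy() / (h * w)


class GlobalMaxPool(Layer):
    """Channel-wise global max: 'does this feature occur anywhere'."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._shape
        g = np.zeros((n, c, h * w), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, gy):
        self.gw[...] = self._x.T @ gy
        self.gb[...] = gy.sum(axis=0)
        return gy @ self.w.T
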