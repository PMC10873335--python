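"""Minimal NumPy layers with hand-written backpropagation.

Everything runs on (N, C, H, W) arrays.  Layers cache what their backward
pass needs during ``forward(train=True)``; ``backward`` accumulates
parameter gradients into ``Parameter.grad`` and returns the gradient with
respect to the layer input.  All randomness (initialization, dropout) is
drawn from the generator handed to the layer, so a fixed seed gives
bit-identical training runs on one machine.

The default dtype is float32; tests use float64 for finite-difference
gradient checks.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter", "Layer", "Conv2d", "ConvTranspose2d", "MaxPool2d",
    "BatchNorm2d", "ReLU", "LeakyReLU", "Sigmoid", "Dropout", "Sequential",
]


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Parameter]:
        return []

    def __call__(self, x, train: bool = True):
        return self.forward(x, train)


class Conv2d(Layer):
    """k x k convolution, 'same' padding (k odd), arbitrary stride.

    init='he' (Kaiming normal) or a float giving the std of a normal.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, init="he",
                 dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        std = math.sqrt(2.0 / (c_in * kernel * kernel)) if init == "he" else float(init)
        self.w = Parameter(rng.normal(0.0, std, (c_out, c_in * kernel * kernel)).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        y = cols @ self.w.data.T + self.b.data
        self._cache = (cols, x.shape, (ho, wo))
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        p, k, s = self.pad, self.k, self.stride
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.w.grad += dym.T @ cols
        self.b.grad += dym.sum(axis=0)
        dcols = (dym @ self.w.data).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Layer):
    """2x upsampling transposed convolution (kernel 2, stride 2)."""

    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None, init="he",
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        std = math.sqrt(2.0 / (c_in * 4)) if init == "he" else float(init)
        self.w = Parameter(rng.normal(0.0, std, (c_in, c_out, 2, 2)).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        self._x = x
        y = np.einsum("nchw,cdij->ndhiwj", x, self.w.data, optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w)
        return y + self.b.data[None, :, None, None]

    def backward(self, dy):
        x = self._x
        n, c, h, w = x.shape
        dyr = dy.reshape(n, self.c_out, h, 2, w, 2)
        self.w.grad += np.einsum("nchw,ndhiwj->cdij", x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("ndhiwj,cdij->nchw", dyr, self.w.data, optimize=True)


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train: bool = True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling needs even spatial size")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = np.ascontiguousarray(win).reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, train)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, invstd, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return dy * g * invstd[None, :, None, None]
        n, _, h, w = dy.shape
        m = n * h * w
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def forward(self, x, train: bool = True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = True):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) \
            / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
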