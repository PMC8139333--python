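"""Minimal convolutional neural-network core on numpy.

Provides exactly the pieces the autoencoder stages need — strided and
transposed 3x3 convolutions, max pooling, dense layers, ReLU/sigmoid, Adam —
with hand-derived backpropagation.  Layers cache what their backward pass
needs; everything is deterministic given the RNG used at initialization and
shuffling.

Array convention: images are (N, C, H, W) float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "sigmoid",
    "numerical_gradient",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _conv_forward(x, W, b, stride, pad):
    N, C, H, Wd = x.shape
    co, ci, k, _ = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    OH, OW = sw.shape[2], sw.shape[3]
    cols = np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(N, OH, OW, C * k * k)
    out = cols @ W.reshape(co, -1).T + b
    return out.transpose(0, 3, 1, 2), (cols, x.shape, W.shape, stride, pad)


def _conv_backward(dout, W, cache):
    cols, x_shape, w_shape, stride, pad = cache
    N, C, H, Wd = x_shape
    co, ci, k, _ = w_shape
    OH, OW = dout.shape[2], dout.shape[3]
    dflat = dout.transpose(0, 2, 3, 1)
    dW = np.einsum("nhwc,nhwk->ck", dflat, cols).reshape(w_shape)
    db = dflat.sum(axis=(0, 1, 2))
    dcols = (dflat @ W.reshape(co, -1)).reshape(N, OH, OW, C, k, k).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((N, C, H + 2 * pad, Wd + 2 * pad))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += dcols[
                :, :, i, j
            ]
    dx = dxp[:, :, pad : pad + H, pad : pad + Wd]
    return dx, dW, db


class Layer:
    def params(self) -> list[list]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (by default) convolution with stride and zero padding."""

    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, (cout, cin, k, k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.stride, self.pad = stride, pad
        self._cache = None

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x):
        out, self._cache = _conv_forward(x, self.W, self.b, self.stride, self.pad)
        return out

    def backward(self, dout):
        dx, dW, db = _conv_backward(dout, self.W, self._cache)
        self.dW[...] = dW
        self.db[...] = db
        return dx


class ConvTranspose2d(Layer):
    """Transposed convolution, implemented as zero-dilation + unit-stride conv.

    With k=3, pad=1, stride=2, output_padding=1 the spatial size exactly
    doubles (the mirror of a stride-2 Conv2d on even sizes).
    """

    def __init__(self, cin, cout, k=3, stride=2, pad=1, output_padding=1, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, (cout, cin, k, k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad, self.outpad = k, stride, pad, output_padding
        self._cache = None

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def _dilate(self, x):
        N, C, H, Wd = x.shape
        s = self.stride
        xd = np.zeros((N, C, (H - 1) * s + 1 + self.outpad, (Wd - 1) * s + 1 + self.outpad))
        xd[:, :, :: s, :: s][:, :, :H, :Wd] = x
        return xd

    def forward(self, x):
        self._in_shape = x.shape
        xd = self._dilate(x)
        out, self._cache = _conv_forward(xd, self.W, self.b, 1, self.k - 1 - self.pad)
        return out

    def backward(self, dout):
        dxd, dW, db = _conv_backward(dout, self.W, self._cache)
        self.dW[...] = dW
        self.db[...] = db
        N, C, H, Wd = self._in_shape
        return dxd[:, :, :: self.stride, :: self.stride][:, :, :H, :Wd]


class Dense(Layer):
    def __init__(self, nin, nout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nout, nin))
        self.b = np.zeros(nout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2d(Layer):
    """2x2 max pooling (even spatial sizes)."""

    def forward(self, x):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H // 2, W // 2, 4
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        N, C, H, W = self._shape
        dxr = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H, W
        )


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape

    def forward(self, x):
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dout):
        return dout.reshape(dout.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def numerical_gradient(f, x, eps=1e-5):
    """Central-difference gradient of a scalar function, for testing layers."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
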