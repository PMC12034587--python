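"""Minimal seeded neural-network engine (numpy).

Implements exactly the layers needed by the reconstruction models used for
patch-level anomaly scoring: 3x3 convolutions, 2x2 max pooling, dense layers,
2x2-stride-2 transposed convolutions, ReLU/sigmoid, MSE loss, and Adam/RMSprop
optimizers. Everything is float32, reverse-mode, and deterministic given the
rng handed to the initializers; backward passes are verified against numerical
gradients in the test suite.

Tensors are NCHW. A layer stores its parameters and, after ``backward``, the
corresponding gradients; optimizers update whatever parameter list they are
bound to, which is how frozen sub-networks (e.g. a trained generator during
encoder training) are expressed: simply do not bind them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ConvTranspose2x2", "MaxPool2x2", "Dense",
    "ReLU", "Sigmoid", "Flatten", "Reshape", "Sequential",
    "Adam", "RMSprop", "mse_loss",
]


class Layer:
    """Base class: stateless layers override forward/backward only."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self):
        """List of (param, grad) array pairs; arrays are updated in place."""
        return []


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), square kernel, zero padding."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = _he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        # (N, C, Hp, Wp) -> (N, oh*ow, C*k*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]          # (N, C, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(xp.shape[0], oh * ow, -1)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - self.k) // self.stride + 1
        ow = (w + 2 * p - self.k) // self.stride + 1
        cols = self._im2col(xp, oh, ow)
        y = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        self._cache = (x.shape, cols, oh, ow)
        return y.transpose(0, 2, 1).reshape(n, self.out_ch, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (xshape, cols, oh, ow) = self._cache
        n, c, h, w = xshape
        p, k, s = self.pad, self.k, self.stride
        g = grad.reshape(n, self.out_ch, oh * ow).transpose(0, 2, 1)  # (N, L, O)
        self.dW[...] = np.tensordot(g, cols, axes=([0, 1], [0, 1])).reshape(self.W.shape)
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.W.reshape(self.out_ch, -1)                   # (N, L, C*k*k)
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2x2(Layer):
    """Transposed convolution, kernel 2, stride 2: exact 2x upsampling.

    Non-overlapping output blocks avoid checkerboard artifacts and make the
    operation a per-pixel linear map followed by a pixel shuffle.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = _he_init(rng, (in_ch, out_ch, 2, 2), in_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,cokl->nohkwl", x, self.W, optimize=True)
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w) + self.b[None, :, None, None]
        return y.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        g = grad.reshape(n, self.out_ch, h, 2, w, 2)
        self.dW[...] = np.einsum("nchw,nohkwl->cokl", x, g, optimize=True)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        return np.einsum("nohkwl,cokl->nchw", g, self.W, optimize=True).astype(np.float32)


class MaxPool2x2(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (xshape, idx) = self._cache
        n, c, h, w = xshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        return (dflat.reshape(n, c, h // 2, w // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        return self._y.astype(np.float32)

    def backward(self, grad):
        return (grad * self._y * (1.0 - self._y)).astype(np.float32)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape  # per-sample shape

    def forward(self, x):
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def __call__(self, x):
        return self.forward(x)


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
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)


class RMSprop:
    def __init__(self, params, lr=5e-5, rho=0.9, eps=1e-8):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for i, (p, g) in enumerate(self.params):
            self.v[i] = self.rho * self.v[i] + (1 - self.rho) * g * g
            p -= (self.lr * g / (np.sqrt(self.v[i]) + self.eps)).astype(p.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over every scalar entry; returns (loss, dL/dpred)."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff * diff))
    grad = (2.0 * diff / diff.size).astype(np.float32)
    return loss, grad
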