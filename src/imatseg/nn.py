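"""Minimal NumPy neural-network engine used by the segmentation and
clustering models.

Layers implement ``forward(x, train)`` and ``backward(grad)``; parameters
and their gradients live on the layer (``W``/``dW`` etc.) and are updated
by :class:`Adam`.  Convolutions use im2col + BLAS matmul; the transposed
convolution is the exact adjoint of the strided convolution, so one pair of
routines serves both directions and every backward pass can be (and is, in
the tests) verified against finite differences.

All computation is float32 for speed; models are deterministic given their
construction seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------------------
# im2col primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride,
                kj:kj + stride * wo:stride] += d[:, :, :, :, ki, kj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv_forward(x, W, b, stride: int, pad: int):
    """x (N,Ci,H,W), W (Co,Ci,k,k) -> y (N,Co,Ho,Wo) plus im2col cache."""
    co, ci, k, _ = W.shape
    cols, ho, wo = _im2col(x, k, stride, pad)
    y = cols @ W.reshape(co, -1).T
    if b is not None:
        y += b
    n = x.shape[0]
    y = y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    return y, (cols, ho, wo)


def conv_backward(gy, x_shape, W, cache, stride: int, pad: int):
    """Gradients of conv_forward: returns (dx, dW, db)."""
    cols, ho, wo = cache
    co = W.shape[0]
    k = W.shape[2]
    gym = gy.transpose(0, 2, 3, 1).reshape(-1, co)
    dW = (gym.T @ cols).reshape(W.shape)
    db = gym.sum(axis=0)
    dcols = gym @ W.reshape(co, -1)
    dx = _col2im(dcols, x_shape, k, stride, pad, ho, wo)
    return dx, dW, db


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base: layers expose (param, grad) pairs for the optimizer."""

    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) convolution, same padding by default, stride 1."""

    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))           # He initialization
        self.W = (rng.standard_normal((cout, cin, k, k)) * scale).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._xshape = x.shape
        y, self._cache = conv_forward(x, self.W, self.b, self.stride, self.pad)
        return y

    def backward(self, gy):
        dx, dW, db = conv_backward(
            gy, self._xshape, self.W, self._cache, self.stride, self.pad
        )
        self.dW += dW
        self.db += db
        return dx


class ConvTranspose2d(Layer):
    """Transposed convolution as the exact adjoint of a strided Conv2d.

    Output size: (H-1)*stride - 2*pad + k + output_padding.
    """

    def __init__(self, cin, cout, k=2, stride=2, pad=0, output_padding=0,
                 rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad, self.op = k, stride, pad, output_padding
        scale = np.sqrt(2.0 / (cin * k * k))
        # stored in "conv orientation": (cin, cout, k, k) so forward is the
        # adjoint of a (cin <- cout) strided convolution
        self.W = (rng.standard_normal((cin, cout, k, k)) * scale).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def out_size(self, h):
        return (h - 1) * self.stride - 2 * self.pad + self.k + self.op

    def forward(self, x, train=True):
        n, cin, h, w = x.shape
        self._x = x
        k, s, p = self.k, self.stride, self.pad
        cout = self.W.shape[1]
        hp, wp = (h - 1) * s + k, (w - 1) * s + k
        ypad = np.zeros((n, cout, hp + self.op, wp + self.op), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                # ypad[:, :, ki + s*i, kj + s*j] += sum_c x[:, c, i, j] W[c, :, ki, kj]
                contrib = np.tensordot(x, self.W[:, :, ki, kj], axes=([1], [0]))
                ypad[:, :, ki:ki + s * h:s, kj:kj + s * w:s] += (
                    contrib.transpose(0, 3, 1, 2)
                )
        ho, wo = self.out_size(h), self.out_size(w)
        y = ypad[:, :, p:p + ho, p:p + wo]
        return y + self.b[None, :, None, None]

    def backward(self, gy):
        n, cin, h, w = self._x.shape
        k, s, p = self.k, self.stride, self.pad
        cout = self.W.shape[1]
        hp, wp = (h - 1) * s + k + self.op, (w - 1) * s + k + self.op
        gpad = np.zeros((n, cout, hp, wp), dtype=F32)
        ho, wo = self.out_size(h), self.out_size(w)
        gpad[:, :, p:p + ho, p:p + wo] = gy
        dx = np.zeros_like(self._x)
        for ki in range(k):
            for kj in range(k):
                gsub = gpad[:, :, ki:ki + s * h:s, kj:kj + s * w:s]
                dx += np.tensordot(
                    gsub, self.W[:, :, ki, kj], axes=([1], [1])
                ).transpose(0, 3, 1, 2)
                self.dW[:, :, ki, kj] += np.tensordot(
                    self._x, gsub, axes=([0, 2, 3], [0, 2, 3])
                )
        self.db += gy.sum(axis=(0, 2, 3))
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // 2, w // 2, 4)
        self._arg = v.argmax(axis=-1)
        self._xshape = x.shape
        return v.max(axis=-1)

    def backward(self, gy):
        n, c, h, w = self._xshape
        gv = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gv, self._arg[..., None], gy[..., None], axis=-1)
        gv = gv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gv.reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, gy):
        return gy * self._m


class Sigmoid(Layer):
    def forward(self, x, train=True):
        # numerically stable two-sided form
        self._y = np.where(
            x >= 0,
            1.0 / (1.0 + np.exp(-np.abs(x))),
            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))),
        ).astype(x.dtype)
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class BatchNorm(Layer):
    """Batch normalization over (N, H, W) per channel (or N for 2-D input)."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1)

    def forward(self, x, train=True):
        ax, sh = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            m = self.momentum
            self.run_mean = (m * self.run_mean + (1 - m) * mean).astype(F32)
            self.run_var = (m * self.run_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).reshape(sh).astype(F32)
        self._xhat = (x - mean.reshape(sh)) * self._istd
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, gy):
        ax, sh = self._axes(gy), self._shape(gy)
        m = gy.size / gy.shape[1] if gy.ndim == 4 else gy.shape[0]
        self.dgamma += (gy * self._xhat).sum(axis=ax)
        self.dbeta += gy.sum(axis=ax)
        gxhat = gy * self.gamma.reshape(sh)
        dx = (self._istd / m) * (
            m * gxhat
            - gxhat.sum(axis=ax).reshape(sh)
            - self._xhat * (gxhat * self._xhat).sum(axis=ax).reshape(sh)
        )
        return dx.astype(F32)


class Dense(Layer):
    def __init__(self, nin, nout, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * scale).astype(F32)
        self.b = np.zeros(nout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy):
        self.dW += self._x.T @ gy
        self.db += gy.sum(axis=0)
        return gy @ self.W.T


class L2Normalize(Layer):
    """Project vectors onto the unit hypersphere (per row)."""

    def __init__(self, eps=1e-12):
        self.eps = eps

    def forward(self, x, train=True):
        self._norm = np.sqrt((x ** 2).sum(axis=1, keepdims=True)) + self.eps
        self._y = x / self._norm
        return self._y

    def backward(self, gy):
        dot = (gy * self._y).sum(axis=1, keepdims=True)
        return (gy - self._y * dot) / self._norm


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape  # per-sample shape

    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy):
        return gy.reshape(self._in)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= (self.lr * (self.m[i] / b1t)
                  / (np.sqrt(self.v[i] / b2t) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0


def count_params(layer: Layer) -> int:
    return int(sum(p.size for p, _ in layer.params()))
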