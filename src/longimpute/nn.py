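"""Minimal 3D convolutional network stack on numpy with analytic backprop.

Everything operates on single examples laid out channel-first,
``(C, D, H, W)`` — the training regime here is batch size 1, so no batch
axis is carried.  Each layer caches what its backward pass needs; calling
``backward`` with the gradient of the loss w.r.t. the layer output returns
the gradient w.r.t. its input and accumulates parameter gradients in
``Param.grad``.

Convolution is computed as a sum of shifted ``tensordot`` contractions
(one per kernel offset), which matches im2col flop-for-flop without
materialising the column matrix.  Two padding modes exist: ``"zeros"``
(default) and ``"circular"``, the latter making shift-equivariance of a
conv/pool/upsample pipeline exact, which the test suite exploits.

Correctness of every backward pass is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "MaxPool3d",
    "UpsampleNearest3d",
    "Sequential",
    "Adam",
]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _as3(v) -> tuple:
    if np.isscalar(v):
        return (int(v),) * 3
    return tuple(int(x) for x in v)


class Conv3d(Layer):
    """3D convolution, kernel k, stride s, explicit per-axis padding.

    ``pad`` is either a scalar (symmetric) or a per-axis (before, after)
    pair; ``pad_mode`` is "zeros" or "circular".  Weights are initialised
    N(0, init_sd) from ``rng``; biases start at zero.
    """

    def __init__(self, cin, cout, kernel=3, stride=1, pad=None, pad_mode="zeros",
                 rng=None, init_sd=0.02, dtype=np.float32):
        self.cin, self.cout = int(cin), int(cout)
        self.kernel = _as3(kernel)
        self.stride = _as3(stride)
        if pad is None:  # "same" for odd kernels at stride 1
            pad = tuple((k - 1) // 2 for k in self.kernel)
        pads = []
        for p in (pad if not np.isscalar(pad) else (pad,) * 3):
            pads.append((int(p), int(p)) if np.isscalar(p) else (int(p[0]), int(p[1])))
        self.pad = tuple(pads)
        if pad_mode not in ("zeros", "circular"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        self.pad_mode = pad_mode
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, init_sd, size=(self.cout, self.cin) + self.kernel)
                       .astype(dtype))
        self.b = Param(np.zeros(self.cout, dtype=dtype))
        self._xp = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    def _out_shape(self, spatial):
        out = []
        for n, k, s, (pb, pa) in zip(spatial, self.kernel, self.stride, self.pad):
            m = (n + pb + pa - k) // s + 1
            if m < 1:
                raise ShapeError(f"input axis {n} too small for kernel {k} pad {(pb, pa)}")
            out.append(m)
        return tuple(out)

    def _pad(self, x):
        widths = ((0, 0),) + self.pad
        if all(p == (0, 0) for p in self.pad):
            return x
        mode = "constant" if self.pad_mode == "zeros" else "wrap"
        return np.pad(x, widths, mode=mode)

    def forward(self, x):
        if x.ndim != 4 or x.shape[0] != self.cin:
            raise ShapeError(f"expected ({self.cin}, D, H, W), got {x.shape}")
        xp = self._pad(x)
        self._xp, self._xshape = xp, x.shape
        Do, Ho, Wo = self._out_shape(x.shape[1:])
        kz_, ky_, kx_ = self.kernel
        sz, sy, sx = self.stride
        W = self.W.value
        y = np.zeros((self.cout, Do, Ho, Wo), dtype=x.dtype)
        for kz in range(kz_):
            for ky in range(ky_):
                for kx in range(kx_):
                    xs = xp[:, kz:kz + sz * Do:sz, ky:ky + sy * Ho:sy, kx:kx + sx * Wo:sx]
                    y += np.tensordot(W[:, :, kz, ky, kx], xs, axes=(1, 0))
        return y + self.b.value[:, None, None, None]

    def backward(self, gy):
        xp = self._xp
        kz_, ky_, kx_ = self.kernel
        sz, sy, sx = self.stride
        Do, Ho, Wo = gy.shape[1:]
        W = self.W.value
        dxp = np.zeros_like(xp)
        for kz in range(kz_):
            for ky in range(ky_):
                for kx in range(kx_):
                    sl = (slice(None), slice(kz, kz + sz * Do, sz),
                          slice(ky, ky + sy * Ho, sy), slice(kx, kx + sx * Wo, sx))
                    xs = xp[sl]
                    self.W.grad[:, :, kz, ky, kx] += np.tensordot(
                        gy, xs, axes=([1, 2, 3], [1, 2, 3]))
                    dxp[sl] += np.tensordot(W[:, :, kz, ky, kx], gy, axes=(0, 0))
        self.b.grad += gy.sum(axis=(1, 2, 3))
        return self._unpad(dxp)

    def _unpad(self, dxp):
        if all(p == (0, 0) for p in self.pad):
            return dxp
        if self.pad_mode == "zeros":
            sl = (slice(None),) + tuple(
                slice(pb, dxp.shape[i + 1] - pa) for i, (pb, pa) in enumerate(self.pad))
            return dxp[sl]
        # circular: fold the pad strips back onto the wrapped positions,
        # reversing np.pad's per-axis order
        g = dxp
        for axis in (3, 2, 1):
            pb, pa = self.pad[axis - 1]
            n = g.shape[axis] - pb - pa
            core = np.take(g, np.arange(pb, pb + n), axis=axis).copy()
            if pb:
                head = np.take(g, np.arange(0, pb), axis=axis)
                idx = [slice(None)] * 4
                idx[axis] = slice(n - pb, n)
                core[tuple(idx)] += head
            if pa:
                tail = np.take(g, np.arange(pb + n, pb + n + pa), axis=axis)
                idx = [slice(None)] * 4
                idx[axis] = slice(0, pa)
                core[tuple(idx)] += tail
            g = core
        return g


class InstanceNorm3d(Layer):
    """Per-channel spatial normalisation, no learned affine (batch size 1)."""

    def __init__(self, eps=1e-5):
        self.eps = eps
        self._xhat = None
        self._istd = None

    def forward(self, x):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        self._xhat, self._istd = xhat, istd
        return xhat

    def backward(self, gy):
        xhat, istd = self._xhat, self._istd
        gmean = gy.mean(axis=(1, 2, 3), keepdims=True)
        gxhat = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return (gy - gmean - xhat * gxhat) * istd


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class MaxPool3d(Layer):
    """2x2x2 max pooling; ties resolve to the first maximal element."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x):
        c, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ShapeError(f"MaxPool3d needs even axes, got {x.shape}")
        xr = x.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
        xt = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, D // 2, H // 2, W // 2, 8)
        self._idx = np.argmax(xt, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xt, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        c, D, H, W = self._shape
        gt = np.zeros((c, D // 2, H // 2, W // 2, 8), dtype=gy.dtype)
        np.put_along_axis(gt, self._idx[..., None], gy[..., None], axis=-1)
        gt = gt.reshape(c, D // 2, H // 2, W // 2, 2, 2, 2)
        return gt.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, D, H, W)


class UpsampleNearest3d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        c, D, H, W = gy.shape
        return gy.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(2, 4, 6))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adam over a fixed parameter list; state keyed by position."""

    def __init__(self, params: list, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (lr / c1) * m / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def zero_grads(params: list):
    for p in params:
        p.zero_grad()


def parameter_count(params: list) -> int:
    return int(sum(p.value.size for p in params))
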