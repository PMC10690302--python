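"""Minimal 3D convolutional network engine (numpy, manual backprop).

Implements exactly what the super-resolution learners need: 'same'-padded
3D convolutions (im2col via sliding windows + BLAS tensordot), leaky ReLU,
voxel-center-aligned trilinear x2 upsampling, residual / dense / cross-stage
-partial blocks, and Adam.  Tensors are (N, C, D, H, W); float32 by default.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3D",
    "LeakyReLU",
    "Upsample3D",
    "Sequential",
    "ResidualBlock",
    "DenseBlock",
    "CSPBlock",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "is_weight")

    def __init__(self, value: np.ndarray, is_weight: bool = True) -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.is_weight = is_weight  # weights (not biases) enter L2 penalty

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """'Same'-padded 3D convolution, stride 1, odd kernel."""

    def __init__(self, cin, cout, k=3, rng=None, zero_init=False,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        if zero_init:
            w = np.zeros((cout, cin, k, k, k), dtype=dtype)
        else:
            rng = rng if rng is not None else np.random.default_rng()
            w = rng.normal(0, np.sqrt(2.0 / fan_in),
                           (cout, cin, k, k, k)).astype(dtype)
        self.weight = Param(w)
        self.bias = Param(np.zeros(cout, dtype=dtype), is_weight=False)
        self._xp = None

    def params(self):
        return [self.weight, self.bias]

    @staticmethod
    def _offsets(k):
        return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]

    def _corr(self, xp, w):
        """Correlate padded input (N,C,*) with kernel w (Cout,C,k,k,k).

        Shift-and-GEMM: one (Cout,C) x (N,C,P) matmul per kernel offset —
        avoids materializing the full im2col tensor.
        """
        k = self.k
        n, cin = xp.shape[:2]
        cout = w.shape[0]
        d, h, wd = (s - k + 1 for s in xp.shape[2:])
        p = d * h * wd
        y = np.zeros((n, cout, p), dtype=xp.dtype)
        for a, b, c in self._offsets(k):
            xv = np.ascontiguousarray(
                xp[:, :, a : a + d, b : b + h, c : c + wd]
            ).reshape(n, cin, p)
            y += w[:, :, a, b, c].astype(xp.dtype, copy=False) @ xv
        return y.reshape(n, cout, d, h, wd)

    def forward(self, x):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp = xp
        y = self._corr(xp, self.weight.value)
        return y + self.bias.value.astype(x.dtype).reshape(1, -1, 1, 1, 1)

    def backward(self, g):
        xp = self._xp
        k, p = self.k, self.k // 2
        self.bias.grad += g.sum(axis=(0, 2, 3, 4)).astype(self.bias.value.dtype)
        # weight gradient: per-offset (N,Cout,P) x (N,P,C) contraction
        n = xp.shape[0]
        d, h, wd = g.shape[2:]
        np_ = d * h * wd
        g2 = g.reshape(n, self.cout, np_)
        gw = np.empty_like(self.weight.value)
        for a, b, c in self._offsets(k):
            xv = np.ascontiguousarray(
                xp[:, :, a : a + d, b : b + h, c : c + wd]
            ).reshape(n, self.cin, np_)
            gw[:, :, a, b, c] = np.matmul(
                g2, xv.transpose(0, 2, 1)
            ).sum(axis=0)
        self.weight.grad += gw
        # input gradient: full correlation of g with the flipped kernel
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        w_flip = np.ascontiguousarray(
            self.weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        gx = self._corr(gp, w_flip)
        self._xp = None
        return gx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)


def _upsample_matrix(n: int, factor: int, dtype) -> np.ndarray:
    """Dense (factor*n, n) voxel-center-aligned linear interpolation map.

    Output voxel i samples source coordinate (i + 0.5)/factor - 0.5, with
    edge clamping.
    """
    pos = (np.arange(factor * n) + 0.5) / factor - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, n - 1)
    i1 = np.clip(np.floor(pos).astype(int) + 1, 0, n - 1)
    w = pos - np.floor(pos)
    mat = np.zeros((factor * n, n), dtype=dtype)
    rows = np.arange(factor * n)
    np.add.at(mat, (rows, i0), 1 - w)
    np.add.at(mat, (rows, i1), w)
    return mat


def upsample_trilinear(x: np.ndarray, factor: int = 2) -> np.ndarray:
    """Trilinear upsampling of (..., D, H, W) by an integer factor."""
    for ax in (-3, -2, -1):
        n = x.shape[ax]
        mat = _upsample_matrix(n, factor, x.dtype)
        x = np.moveaxis(np.moveaxis(x, ax, -1) @ mat.T, -1, ax)
    return x


class Upsample3D(Layer):
    """Trilinear x``factor`` upsampling (parameter-free)."""

    def __init__(self, factor: int = 2):
        self.factor = factor
        self._in_shape = None

    def forward(self, x):
        self._in_shape = x.shape
        return upsample_trilinear(x, self.factor)

    def backward(self, g):
        for ax in (-3, -2, -1):
            n = self._in_shape[ax]
            mat = _upsample_matrix(n, self.factor, g.dtype)
            g = np.moveaxis(np.moveaxis(g, ax, -1) @ mat, -1, ax)
        return g


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class ResidualBlock(Layer):
    """conv-act-conv with an identity skip (channel-preserving)."""

    def __init__(self, channels, k=3, rng=None, alpha=0.1, dtype=np.float32):
        self.branch = Sequential(
            Conv3D(channels, channels, k, rng, dtype=dtype),
            LeakyReLU(alpha),
            Conv3D(channels, channels, k, rng, dtype=dtype),
        )
        self.act = LeakyReLU(alpha)

    def params(self):
        return self.branch.params()

    def forward(self, x):
        return self.act.forward(x + self.branch.forward(x))

    def backward(self, g):
        g = self.act.backward(g)
        return g + self.branch.backward(g)


class DenseBlock(Layer):
    """Two convs whose input is re-concatenated, fused by a 1x1 conv."""

    def __init__(self, channels, k=3, rng=None, alpha=0.1, dtype=np.float32):
        self.c = channels
        self.branch = Sequential(
            Conv3D(channels, channels, k, rng, dtype=dtype),
            LeakyReLU(alpha),
            Conv3D(channels, channels, k, rng, dtype=dtype),
            LeakyReLU(alpha),
        )
        self.fuse = Conv3D(2 * channels, channels, 1, rng, dtype=dtype)

    def params(self):
        return self.branch.params() + self.fuse.params()

    def forward(self, x):
        h = self.branch.forward(x)
        return self.fuse.forward(np.concatenate([x, h], axis=1))

    def backward(self, g):
        g = self.fuse.backward(g)
        gx, gh = g[:, : self.c], g[:, self.c :]
        return gx + self.branch.backward(gh)


class CSPBlock(Layer):
    """Cross-stage-partial block: half the channels bypass the conv path."""

    def __init__(self, channels, k=3, rng=None, alpha=0.1, dtype=np.float32):
        if channels % 2:
            raise ValueError("CSP block requires an even channel count")
        self.half = channels // 2
        self.branch = Sequential(
            Conv3D(self.half, self.half, k, rng, dtype=dtype),
            LeakyReLU(alpha),
            Conv3D(self.half, self.half, k, rng, dtype=dtype),
        )
        self.fuse = Conv3D(channels, channels, 1, rng, dtype=dtype)

    def params(self):
        return self.branch.params() + self.fuse.params()

    def forward(self, x):
        x1, x2 = x[:, : self.half], x[:, self.half :]
        h = self.branch.forward(np.ascontiguousarray(x2))
        return self.fuse.forward(np.concatenate([x1, h], axis=1))

    def backward(self, g):
        g = self.fuse.backward(g)
        g1, gh = g[:, : self.half], g[:, self.half :]
        g2 = self.branch.backward(np.ascontiguousarray(gh))
        return np.concatenate([g1, g2], axis=1)


BLOCK_TYPES = {
    "residual": ResidualBlock,
    "dense": DenseBlock,
    "csp": CSPBlock,
}


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype
            )
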