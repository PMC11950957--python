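"""Minimal NumPy neural-network layers for 2D image-to-image regression.

Implements exactly what the dose-prediction U-net needs — 2D convolution,
batch normalisation, ReLU, dropout, nearest-neighbour upsampling — with
explicit forward/backward passes and an Adam optimiser.  Everything is
float32 and channels-first ``(C, B, H, W)`` internally: a convolution is
one im2col buffer build plus a single BLAS GEMM forward, and two GEMMs
plus a col2im accumulation backward (the buffer is cached between the
passes, so the input patches are gathered exactly once per step).

These layers are deliberately small in scope (no autograd graph, no GPU);
they exist so the dose model is self-contained and exactly reproducible
from a seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# numba convolution kernels (float32, channels-first, single-threaded)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _conv33(xp, Wk, b, y):
    """3x3 stride-1 convolution; xp is the 1-padded input (cin,B,H+2,W+2)."""
    cin, B, Hp, Wp = xp.shape
    cout = y.shape[0]
    H, W = Hp - 2, Wp - 2
    for bi in range(B):
        for i in range(H):
            for co in range(cout):
                yrow = y[co, bi, i]
                for j in range(W):
                    yrow[j] = b[co]
            for di in range(3):
                for ci in range(cin):
                    xrow = xp[ci, bi, i + di]
                    for co in range(cout):
                        w0 = Wk[di, 0, ci, co]
                        w1 = Wk[di, 1, ci, co]
                        w2 = Wk[di, 2, ci, co]
                        yrow = y[co, bi, i]
                        for j in range(W):
                            yrow[j] += w0 * xrow[j] + w1 * xrow[j + 1] + w2 * xrow[j + 2]


@njit(cache=True, fastmath=True)
def _dw33(xp, dy, dW):
    """Accumulate the 3x3 weight gradient: dW[di,dj,ci,co] += sum xp*dy."""
    cin, B, Hp, Wp = xp.shape
    cout = dy.shape[0]
    H, W = Hp - 2, Wp - 2
    for bi in range(B):
        for i in range(H):
            for di in range(3):
                for ci in range(cin):
                    xrow = xp[ci, bi, i + di]
                    for co in range(cout):
                        dyrow = dy[co, bi, i]
                        a0 = np.float32(0.0)
                        a1 = np.float32(0.0)
                        a2 = np.float32(0.0)
                        for j in range(W):
                            d = dyrow[j]
                            a0 += xrow[j] * d
                            a1 += xrow[j + 1] * d
                            a2 += xrow[j + 2] * d
                        dW[di, 0, ci, co] += a0
                        dW[di, 1, ci, co] += a1
                        dW[di, 2, ci, co] += a2


@njit(cache=True, fastmath=True)
def _conv22(x, Wk, b, y):
    """2x2 stride-2 convolution (downsampling)."""
    cin, B, H, W = x.shape
    cout = y.shape[0]
    Ho, Wo = H // 2, W // 2
    for bi in range(B):
        for i in range(Ho):
            for co in range(cout):
                yrow = y[co, bi, i]
                for j in range(Wo):
                    yrow[j] = b[co]
            for di in range(2):
                for ci in range(cin):
                    xrow = x[ci, bi, 2 * i + di]
                    for co in range(cout):
                        w0 = Wk[di, 0, ci, co]
                        w1 = Wk[di, 1, ci, co]
                        yrow = y[co, bi, i]
                        for j in range(Wo):
                            yrow[j] += w0 * xrow[2 * j] + w1 * xrow[2 * j + 1]


@njit(cache=True, fastmath=True)
def _dx22(dy, Wk, dx):
    """Input gradient of the 2x2 stride-2 convolution (overwrites dx)."""
    cout, B, Ho, Wo = dy.shape
    cin = dx.shape[0]
    for bi in range(B):
        for i in range(Ho):
            for ci in range(cin):
                r0 = dx[ci, bi, 2 * i]
                r1 = dx[ci, bi, 2 * i + 1]
                for j in range(Wo):
                    s00 = np.float32(0.0)
                    s01 = np.float32(0.0)
                    s10 = np.float32(0.0)
                    s11 = np.float32(0.0)
                    for co in range(cout):
                        d = dy[co, bi, i, j]
                        s00 += Wk[0, 0, ci, co] * d
                        s01 += Wk[0, 1, ci, co] * d
                        s10 += Wk[1, 0, ci, co] * d
                        s11 += Wk[1, 1, ci, co] * d
                    r0[2 * j] = s00
                    r0[2 * j + 1] = s01
                    r1[2 * j] = s10
                    r1[2 * j + 1] = s11


@njit(cache=True, fastmath=True)
def _dw22(x, dy, dW):
    """Accumulate the 2x2 stride-2 weight gradient."""
    cin, B, H, W = x.shape
    cout, _, Ho, Wo = dy.shape
    for bi in range(B):
        for i in range(Ho):
            for di in range(2):
                for ci in range(cin):
                    xrow = x[ci, bi, 2 * i + di]
                    for co in range(cout):
                        dyrow = dy[co, bi, i]
                        a0 = np.float32(0.0)
                        a1 = np.float32(0.0)
                        for j in range(Wo):
                            d = dyrow[j]
                            a0 += xrow[2 * j] * d
                            a1 += xrow[2 * j + 1] * d
                        dW[di, 0, ci, co] += a0
                        dW[di, 1, ci, co] += a1


class Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adaptive moment estimation over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            g = p.grad
            if self.wd:
                g = g + self.wd * p.value
            p.m *= self.b1
            p.m += (1.0 - self.b1) * g
            p.v *= self.b2
            p.v += (1.0 - self.b2) * np.square(g)
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """k x k convolution, 'same' geometry (output size = input / stride).

    He-initialised; weights are stored (k, k, cin, cout).  Three kernel
    geometries cover the U-net: 3x3 stride 1 ('same', via the direct numba
    kernel), 2x2 stride 2 (downsampling) and 1x1 (projection, via GEMM).
    Tensors are (C, B, H, W) float32.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if (k, stride) not in {(3, 1), (2, 2), (1, 1)}:
            raise ValueError(f"unsupported conv geometry k={k}, stride={stride}")
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (k * k * cin))
        self.W = Param(rng.normal(0.0, std, (k, k, cin, cout)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cin, B, H, Wd = x.shape
        k, s, cout = self.k, self.stride, self.cout
        if H % s or Wd % s:
            raise ValueError(f"spatial size ({H},{Wd}) not divisible by stride {s}")
        if k == 3:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            y = np.empty((cout, B, H, Wd), dtype=np.float32)
            _conv33(xp, self.W.value, self.b.value, y)
            if train:
                self._x = xp
        elif k == 2:
            x = np.ascontiguousarray(x)
            y = np.empty((cout, B, H // 2, Wd // 2), dtype=np.float32)
            _conv22(x, self.W.value, self.b.value, y)
            if train:
                self._x = x
        else:  # 1x1
            x = np.ascontiguousarray(x)
            w = self.W.value.reshape(cin, cout)
            y = (w.T @ x.reshape(cin, -1) + self.b.value[:, None]).reshape(cout, B, H, Wd)
            if train:
                self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cout, B, Ho, Wo = dy.shape
        k, cin = self.k, self.cin
        dy = np.ascontiguousarray(dy)
        self.b.grad += dy.sum(axis=(1, 2, 3))
        x = self._x
        self._x = None
        if k == 3:
            _dw33(x, dy, self.W.grad)
            # input gradient = correlation of dy with the flipped, transposed
            # kernel; reuse the forward kernel
            wt = np.ascontiguousarray(self.W.value[::-1, ::-1].transpose(0, 1, 3, 2))
            dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
            dx = np.empty((cin, B, Ho, Wo), dtype=np.float32)
            _conv33(dyp, wt, np.zeros(cin, dtype=np.float32), dx)
            return dx
        if k == 2:
            _dw22(x, dy, self.W.grad)
            dx = np.empty((cin, B, 2 * Ho, 2 * Wo), dtype=np.float32)
            _dx22(dy, self.W.value, dx)
            return dx
        w = self.W.value.reshape(cin, cout)
        dy2 = dy.reshape(cout, -1)
        self.W.grad += (x.reshape(cin, -1) @ dy2.T).reshape(self.W.grad.shape)
        return (w @ dy2).reshape(cin, B, Ho, Wo)


class BatchNorm(Layer):
    """Per-channel batch normalisation over (B, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[0]
        x2 = x.reshape(c, -1)
        if train:
            n = x2.shape[1]
            mean = x2.mean(axis=1)
            var = np.einsum("ij,ij->i", x2, x2) / n - mean * mean
            var = np.maximum(var, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        scale = (self.gamma.value * ivar).astype(np.float32)
        shift = (self.beta.value - scale * mean).astype(np.float32)
        if train:
            # normalise in place (the conv output feeding a BN is a
            # temporary) and cache xhat for the backward pass
            x2 -= mean.astype(np.float32)[:, None]
            x2 *= ivar.astype(np.float32)[:, None]
            self._xhat, self._ivar = x2, ivar.astype(np.float32)
            y = x2 * self.gamma.value[:, None]
            y += self.beta.value[:, None]
        else:
            y = x2 * scale[:, None]
            y += shift[:, None]
        return y.reshape(x.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = dy.shape[0]
        dy2 = dy.reshape(c, -1)
        n = dy2.shape[1]
        xhat = self._xhat
        dgamma = np.einsum("ij,ij->i", dy2, xhat)
        self.gamma.grad += dgamma
        self.beta.grad += dy2.sum(axis=1)
        g = (self.gamma.value * self._ivar)[:, None]
        # reuse xhat's buffer for the correction term
        xhat *= (dgamma / n).astype(np.float32)[:, None]
        dx2 = dy2 - dy2.mean(axis=1).astype(np.float32)[:, None]
        dx2 -= xhat
        dx2 *= g
        self._xhat = None
        return dx2.reshape(dy.shape)


class ReLU(Layer):
    """Rectifier; applied in place (its input is always a fresh temporary)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, np.float32(0.0), out=x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep) / np.float32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling on (C, B, H, W)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, B, H, Wd = dy.shape
        return dy.reshape(C, B, H // 2, 2, Wd // 2, 2).sum(axis=(3, 5))


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 / diff.size) * diff
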