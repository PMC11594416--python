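"""Numerical kernels for the small CNN.

Convolution (3x3, valid, stride 1) and 2x2 max pooling are numba-jitted
loops over an NCHW layout with row-contiguous inner loops; dense layers,
Adam, and the loss live in NumPy/BLAS.  float32 throughout.  Everything is
single threaded and deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(F32)


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, shape).astype(F32)


# ---------------------------------------------------------------------------
# convolution: x (B,Cin,H,W), W (F,Cin,3,3), b (F,) -> out (B,F,H-2,W-2)
# ---------------------------------------------------------------------------

@njit(fastmath=True, cache=True)
def _conv_fwd(x, W, b, out, relu):
    B, Cin, H, Wd = x.shape
    F = W.shape[0]
    Ho, Wo = H - 2, Wd - 2
    for bi in range(B):
        for f in range(F):
            o = out[bi, f]
            for yo in range(Ho):
                for xo in range(Wo):
                    o[yo, xo] = b[f]
            for ci in range(Cin):
                xc = x[bi, ci]
                w = W[f, ci]
                w00, w01, w02 = w[0, 0], w[0, 1], w[0, 2]
                w10, w11, w12 = w[1, 0], w[1, 1], w[1, 2]
                w20, w21, w22 = w[2, 0], w[2, 1], w[2, 2]
                for yo in range(Ho):
                    r0, r1, r2 = xc[yo], xc[yo + 1], xc[yo + 2]
                    orow = o[yo]
                    for xo in range(Wo):
                        orow[xo] += (w00 * r0[xo] + w01 * r0[xo + 1] + w02 * r0[xo + 2]
                                     + w10 * r1[xo] + w11 * r1[xo + 1] + w12 * r1[xo + 2]
                                     + w20 * r2[xo] + w21 * r2[xo + 1] + w22 * r2[xo + 2])
            if relu:
                for yo in range(Ho):
                    for xo in range(Wo):
                        if o[yo, xo] < 0.0:
                            o[yo, xo] = 0.0


@njit(fastmath=True, cache=True)
def _conv_dw(x, dout, dW, db):
    B, Cin, H, Wd = x.shape
    F = dout.shape[1]
    Ho, Wo = H - 2, Wd - 2
    for f in range(F):
        s = 0.0
        for bi in range(B):
            d = dout[bi, f]
            for yo in range(Ho):
                for xo in range(Wo):
                    s += d[yo, xo]
        db[f] = s
    for bi in range(B):
        for f in range(F):
            d = dout[bi, f]
            for ci in range(Cin):
                xc = x[bi, ci]
                s00 = s01 = s02 = s10 = s11 = s12 = s20 = s21 = s22 = 0.0
                for yo in range(Ho):
                    r0, r1, r2 = xc[yo], xc[yo + 1], xc[yo + 2]
                    drow = d[yo]
                    for xo in range(Wo):
                        v = drow[xo]
                        s00 += v * r0[xo]
                        s01 += v * r0[xo + 1]
                        s02 += v * r0[xo + 2]
                        s10 += v * r1[xo]
                        s11 += v * r1[xo + 1]
                        s12 += v * r1[xo + 2]
                        s20 += v * r2[xo]
                        s21 += v * r2[xo + 1]
                        s22 += v * r2[xo + 2]
                dWf = dW[f, ci]
                dWf[0, 0] += s00
                dWf[0, 1] += s01
                dWf[0, 2] += s02
                dWf[1, 0] += s10
                dWf[1, 1] += s11
                dWf[1, 2] += s12
                dWf[2, 0] += s20
                dWf[2, 1] += s21
                dWf[2, 2] += s22


@njit(fastmath=True, cache=True)
def _conv_dx(dout, W, dx):
    # full correlation with the flipped kernel, via a zero-padded copy of
    # dout so the inner loop is a pure gather (vectorizable)
    B, F, Ho, Wo = dout.shape
    Cin = W.shape[1]
    H, Wd = Ho + 2, Wo + 2
    dpad = np.zeros((Ho + 4, Wo + 4), dtype=dout.dtype)
    for bi in range(B):
        for f in range(F):
            d = dout[bi, f]
            for yo in range(Ho):
                for xo in range(Wo):
                    dpad[yo + 2, xo + 2] = d[yo, xo]
            for ci in range(Cin):
                w = W[f, ci]
                # flipped kernel
                w00, w01, w02 = w[2, 2], w[2, 1], w[2, 0]
                w10, w11, w12 = w[1, 2], w[1, 1], w[1, 0]
                w20, w21, w22 = w[0, 2], w[0, 1], w[0, 0]
                plane = dx[bi, ci]
                for y in range(H):
                    r0, r1, r2 = dpad[y], dpad[y + 1], dpad[y + 2]
                    prow = plane[y]
                    for x_ in range(Wd):
                        prow[x_] += (w00 * r0[x_] + w01 * r0[x_ + 1] + w02 * r0[x_ + 2]
                                     + w10 * r1[x_] + w11 * r1[x_ + 1] + w12 * r1[x_ + 2]
                                     + w20 * r2[x_] + w21 * r2[x_ + 1] + w22 * r2[x_ + 2])


def conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, relu: bool = True):
    B, Cin, H, Wd = x.shape
    F = W.shape[0]
    out = np.empty((B, F, H - 2, Wd - 2), F32)
    _conv_fwd(x, W, b, out, relu)
    return out, (x, out if relu else None)


def conv_backward(dout: np.ndarray, W: np.ndarray, cache, need_dx: bool = True):
    """dout is the gradient at the (post-ReLU, if fused) conv output; the
    ReLU mask is applied here from the cached activations."""
    x, act = cache
    if act is not None:
        dout = np.where(act > 0, dout, F32(0.0))
    dout = np.ascontiguousarray(dout, F32)
    dW = np.zeros_like(W)
    db = np.zeros(W.shape[0], F32)
    _conv_dw(x, dout, dW, db)
    dx = None
    if need_dx:
        dx = np.zeros(x.shape, F32)
        _conv_dx(dout, W, dx)
    return dx, dW, db


# ---------------------------------------------------------------------------
# 2x2 max pooling, stride 2 (floor semantics: trailing row/col dropped)
# ---------------------------------------------------------------------------

@njit(fastmath=True, cache=True)
def _pool_fwd(x, out):
    B, C, H2, W2 = out.shape
    for bi in range(B):
        for c in range(C):
            xc = x[bi, c]
            o = out[bi, c]
            for yo in range(H2):
                r0 = xc[2 * yo]
                r1 = xc[2 * yo + 1]
                for xo in range(W2):
                    m = r0[2 * xo]
                    if r0[2 * xo + 1] > m:
                        m = r0[2 * xo + 1]
                    if r1[2 * xo] > m:
                        m = r1[2 * xo]
                    if r1[2 * xo + 1] > m:
                        m = r1[2 * xo + 1]
                    o[yo, xo] = m


@njit(fastmath=True, cache=True)
def _pool_bwd(x, out, dout, dx):
    # gradient to the first cell attaining the max (fixed scan order)
    B, C, H2, W2 = out.shape
    for bi in range(B):
        for c in range(C):
            xc = x[bi, c]
            o = out[bi, c]
            d = dout[bi, c]
            g = dx[bi, c]
            for yo in range(H2):
                for xo in range(W2):
                    m = o[yo, xo]
                    dv = d[yo, xo]
                    if xc[2 * yo, 2 * xo] == m:
                        g[2 * yo, 2 * xo] += dv
                    elif xc[2 * yo, 2 * xo + 1] == m:
                        g[2 * yo, 2 * xo + 1] += dv
                    elif xc[2 * yo + 1, 2 * xo] == m:
                        g[2 * yo + 1, 2 * xo] += dv
                    else:
                        g[2 * yo + 1, 2 * xo + 1] += dv


def maxpool_forward(x: np.ndarray):
    B, C, H, Wd = x.shape
    out = np.empty((B, C, H // 2, Wd // 2), F32)
    _pool_fwd(x, out)
    return out, (x, out)


def maxpool_backward(dout: np.ndarray, cache):
    x, out = cache
    dx = np.zeros(x.shape, F32)
    _pool_bwd(x, out, np.ascontiguousarray(dout, F32), dx)
    return dx


# ---------------------------------------------------------------------------
# optimizer and loss
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, epsilon: float = 1e-8):
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, epsilon
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            p -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(a: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    a = np.clip(a, eps, 1 - eps)
    return float(-np.mean(y * np.log(a) + (1 - y) * np.log(1 - a)))
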