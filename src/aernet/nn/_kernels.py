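"""Compiled inner loops for the convolution operator.

Direct-convolution kernels JIT-compiled with numba; the autograd module
falls back to pure-numpy im2col when numba is unavailable.  Loop order keeps
the innermost traversal contiguous in memory.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True, fastmath=True)
def conv_fwd(xp, w, stride, ho, wo):
    n, c, hp, wp = xp.shape
    co, _, kh, kw = w.shape
    out = np.zeros((n, co, ho, wo), dtype=xp.dtype)
    for ni in range(n):
        for o in range(co):
            for ci in range(c):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, ci, i, j]
                        for y in range(ho):
                            xrow = xp[ni, ci, y * stride + i]
                            orow = out[ni, o, y]
                            for xj in range(wo):
                                orow[xj] += wv * xrow[xj * stride + j]
    return out


@njit(cache=True, fastmath=True)
def conv_bwd_x(g, w, stride, hp, wp):
    n, co, ho, wo = g.shape
    _, c, kh, kw = w.shape
    gxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
    for ni in range(n):
        for o in range(co):
            for ci in range(c):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, ci, i, j]
                        for y in range(ho):
                            grow = g[ni, o, y]
                            xrow = gxp[ni, ci, y * stride + i]
                            for xj in range(wo):
                                xrow[xj * stride + j] += wv * grow[xj]
    return gxp


@njit(cache=True, fastmath=True)
def conv_bwd_w(g, xp, stride, kh, kw):
    n, co, ho, wo = g.shape
    c = xp.shape[1]
    gw = np.zeros((co, c, kh, kw), dtype=g.dtype)
    for ni in range(n):
        for o in range(co):
            for ci in range(c):
                for i in range(kh):
                    for j in range(kw):
                        acc = 0.0
                        for y in range(ho):
                            grow = g[ni, o, y]
                            xrow = xp[ni, ci, y * stride + i]
                            for xj in range(wo):
                                acc += grow[xj] * xrow[xj * stride + j]
                        gw[o, ci, i, j] += acc
    return gw


@njit(cache=True, fastmath=True)
def bn_fwd_train(x, gamma, beta, eps):
    n, c, h, w = x.shape
    count = n * h * w
    mu = np.zeros(c, dtype=x.dtype)
    var = np.zeros(c, dtype=x.dtype)
    for ci in range(c):
        s = 0.0
        for ni in range(n):
            for y in range(h):
                row = x[ni, ci, y]
                for xi in range(w):
                    s += row[xi]
        m = s / count
        v = 0.0
        for ni in range(n):
            for y in range(h):
                row = x[ni, ci, y]
                for xi in range(w):
                    d = row[xi] - m
                    v += d * d
        mu[ci] = m
        var[ci] = v / count
    out = np.empty_like(x)
    xhat = np.empty_like(x)
    for ci in range(c):
        inv = 1.0 / np.sqrt(var[ci] + eps)
        g, b = gamma[ci], beta[ci]
        m = mu[ci]
        for ni in range(n):
            for y in range(h):
                xrow = x[ni, ci, y]
                hrow = xhat[ni, ci, y]
                orow = out[ni, ci, y]
                for xi in range(w):
                    xh = (xrow[xi] - m) * inv
                    hrow[xi] = xh
                    orow[xi] = g * xh + b
    return out, xhat, mu, var


@njit(cache=True, fastmath=True)
def bn_bwd_train(g, xhat, gamma, inv_std):
    n, c, h, w = g.shape
    count = n * h * w
    ggamma = np.zeros(c, dtype=g.dtype)
    gbeta = np.zeros(c, dtype=g.dtype)
    gx = np.empty_like(g)
    for ci in range(c):
        s1 = 0.0  # sum of g*gamma (via sum g)
        s2 = 0.0  # sum of g*xhat
        for ni in range(n):
            for y in range(h):
                grow = g[ni, ci, y]
                hrow = xhat[ni, ci, y]
                for xi in range(w):
                    s1 += grow[xi]
                    s2 += grow[xi] * hrow[xi]
        ggamma[ci] = s2
        gbeta[ci] = s1
        gm = gamma[ci]
        mean_g = s1 / count
        mean_gx = s2 / count
        inv = inv_std[ci]
        for ni in range(n):
            for y in range(h):
                grow = g[ni, ci, y]
                hrow = xhat[ni, ci, y]
                orow = gx[ni, ci, y]
                for xi in range(w):
                    orow[xi] = inv * gm * (
                        grow[xi] - mean_g - hrow[xi] * mean_gx
                    )
    return gx, ggamma, gbeta
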