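"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style, but vectorized: every
:class:`Tensor` wraps an ``ndarray`` and records the operation that produced
it.  Gradients are accumulated by a reverse topological sweep.  Only the
operations the segmentation network needs are implemented — elementwise
arithmetic with broadcasting, the usual nonlinearities, axis reductions,
slicing/concatenation, im2col-based 2-D convolution, 2x2 max pooling,
nearest-neighbour upsampling and batch normalization.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = [
    "Tensor",
    "no_grad",
    "as_tensor",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample_nearest2x",
    "batchnorm2d",
]


_grad_enabled = True


class no_grad:
    """Context manager: ops inside build no graph, freeing intermediates.

    Used for inference-mode forwards where activations would otherwise be
    pinned by backward closures.
    """

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        if not _grad_enabled:
            parents = ()
            backward = None
            requires_grad = False
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd machinery --------------------------------------------------
    def _accumulate(self, g):
        # First contribution is stored by reference; later ones add
        # out-of-place so shared gradient arrays are never mutated.
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            _unbroadcast_into(self, g)
            _unbroadcast_into(other, g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            _unbroadcast_into(self, -g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            _unbroadcast_into(self, g * other.data)
            _unbroadcast_into(other, g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g):
            _unbroadcast_into(self, g / other.data)
            _unbroadcast_into(other, -g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        def bwd(g):
            _unbroadcast_into(self, g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bwd)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            _unbroadcast_into(self, g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            _unbroadcast_into(self, g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            _unbroadcast_into(self, g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            _unbroadcast_into(self, g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def clip_min(self, floor: float):
        """max(x, floor); gradient passes where x > floor."""
        mask = self.data > floor

        def bwd(g):
            _unbroadcast_into(self, g * mask)

        return Tensor(np.maximum(self.data, floor), parents=(self,), backward=bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            _unbroadcast_into(self, np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            parents=(self,),
            backward=bwd,
        )

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis, keepdims=False):
        axes = axis if isinstance(axis, tuple) else (axis,)
        out_data = self.data.max(axis=axes, keepdims=True)
        mask = (self.data == out_data).astype(self.data.dtype)
        # split ties evenly so the gradient stays well-defined
        mask = mask / mask.sum(axis=axes, keepdims=True)

        def bwd(g):
            gg = g if keepdims else np.reshape(g, out_data.shape)
            _unbroadcast_into(self, gg * mask)

        result = out_data if keepdims else np.squeeze(out_data, axis=axes)
        return Tensor(result, parents=(self,), backward=bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bwd(g):
            _unbroadcast_into(self, g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _unbroadcast_into(self, full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast_into(t: Tensor, g: np.ndarray):
    """Reduce gradient ``g`` back to ``t``'s shape (reverse of broadcasting)."""
    if not t.requires_grad:
        return
    shape = t.data.shape
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ts) in enumerate(zip(g.shape, shape)):
        if ts == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    t._accumulate(g)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _unbroadcast_into(t, g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


# -- convolution -------------------------------------------------------------


def _same_padding(size: int, k: int, stride: int) -> tuple[int, int]:
    """TF-style SAME padding: output = ceil(size / stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, SAME padding.

    ``w`` has shape (C_out, C_in, kh, kw).  Output spatial size is
    ceil(H / stride) x ceil(W / stride).  1x1 kernels take a pure-GEMM fast
    path; general kernels use im2col forward and a shift-and-GEMM backward.
    """
    n, c, h, wid = x.data.shape
    c_out, c_in, kh, kw = w.data.shape
    if c != c_in:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c_in}")
    if kh == 1 and kw == 1:
        return _conv1x1(x, w, b, stride)
    pt, pb = _same_padding(h, kh, stride)
    pl, pr = _same_padding(wid, kw, stride)
    if pt or pb or pl or pr:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if _kernels.HAVE_NUMBA:
        xp = np.ascontiguousarray(xp)
        out = _kernels.conv_fwd(xp, w.data, stride, ho, wo)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        windows = windows[:, :, ::stride, ::stride]  # N, C, Ho, Wo, kh, kw
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
        wmat = w.data.reshape(c_out, c * kh * kw)
        out = cols @ wmat.T  # N, Ho*Wo, C_out
        out = out.transpose(0, 2, 1).reshape(n, c_out, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, c_out, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g = np.ascontiguousarray(g)
        if w.requires_grad:
            if _kernels.HAVE_NUMBA:
                gw = _kernels.conv_bwd_w(g, xp, stride, kh, kw)
            else:
                gmat = np.ascontiguousarray(
                    g.reshape(n, c_out, ho * wo).transpose(0, 2, 1)
                )
                gw = (
                    gmat.reshape(n * ho * wo, c_out).T
                    @ cols.reshape(n * ho * wo, -1)
                ).reshape(w.data.shape)
            _unbroadcast_into(w, gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _unbroadcast_into(b, g.sum(axis=(0, 2, 3)).reshape(b.data.shape))
        if x.requires_grad:
            if _kernels.HAVE_NUMBA:
                gxp = _kernels.conv_bwd_x(g, w.data, stride, hp, wp)
            else:
                gflat = g.reshape(n, c_out, ho * wo)
                gxp = np.zeros((n, c, hp, wp), dtype=xp.dtype)
                for i in range(kh):
                    for j in range(kw):
                        contrib = np.matmul(w.data[:, :, i, j].T, gflat)
                        gxp[
                            :,
                            :,
                            i : i + stride * ho : stride,
                            j : j + stride * wo : stride,
                        ] += contrib.reshape(n, c, ho, wo)
            _unbroadcast_into(x, gxp[:, :, pt : pt + h, pl : pl + wid])

    return Tensor(out, parents=parents, backward=bwd)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """1x1 convolution as a batched channel GEMM (stride = subsampling)."""
    n, c, h, wid = x.data.shape
    c_out = w.data.shape[0]
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    ho, wo = xs.shape[2], xs.shape[3]
    xflat = np.ascontiguousarray(xs).reshape(n, c, ho * wo)
    w2 = w.data.reshape(c_out, c)
    out = np.matmul(w2, xflat).reshape(n, c_out, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, c_out, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gflat = g.reshape(n, c_out, ho * wo)
        if w.requires_grad:
            gw = np.matmul(gflat, xflat.transpose(0, 2, 1)).sum(axis=0)
            _unbroadcast_into(w, gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _unbroadcast_into(b, g.sum(axis=(0, 2, 3)).reshape(b.data.shape))
        if x.requires_grad:
            gxs = np.matmul(w2.T, gflat).reshape(n, c, ho, wo)
            if stride == 1:
                gx = gxs
            else:
                gx = np.zeros_like(x.data)
                gx[:, :, ::stride, ::stride] = gxs
            _unbroadcast_into(x, gx)

    return Tensor(out, parents=parents, backward=bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; requires even spatial size."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial size, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = blocks.max(axis=(3, 5))
    mask = blocks == out[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)

    def bwd(g):
        gb = mask * g[:, :, :, None, :, None]
        _unbroadcast_into(x, gb.reshape(n, c, h, w))

    return Tensor(out, parents=(x,), backward=bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        gb = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        _unbroadcast_into(x, gb)

    return Tensor(out, parents=(x,), backward=bwd)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    c = x.data.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        if _kernels.HAVE_NUMBA:
            out, xhat, mu, var = _kernels.bn_fwd_train(
                np.ascontiguousarray(x.data),
                gamma.data.astype(x.data.dtype),
                beta.data.astype(x.data.dtype),
                x.data.dtype.type(eps),
            )
        else:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            xhat = (x.data - mu.reshape(gshape)) / np.sqrt(
                var.reshape(gshape) + eps
            )
            out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
        inv_std = 1.0 / np.sqrt(var + eps)

        def bwd(g):
            g = np.ascontiguousarray(g)
            if _kernels.HAVE_NUMBA:
                gx, ggamma, gbeta = _kernels.bn_bwd_train(
                    g, xhat, gamma.data.astype(g.dtype), inv_std.astype(g.dtype)
                )
            else:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gxhat = g * gamma.data.reshape(gshape)
                t1 = gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                t2 = xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                gx = inv_std.reshape(gshape) * (t1 - t2)
                ggamma = (g * xhat).sum(axis=(0, 2, 3))
                gbeta = g.sum(axis=(0, 2, 3))
            if gamma.requires_grad:
                _unbroadcast_into(gamma, ggamma)
            if beta.requires_grad:
                _unbroadcast_into(beta, gbeta)
            if x.requires_grad:
                _unbroadcast_into(x, gx)

        return Tensor(out, parents=(x, gamma, beta), backward=bwd)

    # eval mode: affine transform with the running statistics
    inv_std = 1.0 / np.sqrt(running_var + eps)
    xhat = (x.data - running_mean.reshape(gshape)) * inv_std.reshape(gshape)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def bwd(g):
        if gamma.requires_grad:
            _unbroadcast_into(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _unbroadcast_into(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            _unbroadcast_into(
                x, g * gamma.data.reshape(gshape) * inv_std.reshape(gshape)
            )

    return Tensor(out, parents=(x, gamma, beta), backward=bwd)
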