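"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the tensor operations the segmentation network
needs: broadcast arithmetic, matmul, 2-D convolution (stride 1, arbitrary
dilation), 2x2 max/average pooling, bilinear x2 upsampling, batch
normalization, softmax, and elementwise nonlinearities.  Gradients are
accumulated by topological traversal of the recorded graph.

Convolution is computed as an im2col GEMM; its input gradient is itself a
convolution with the spatially flipped, channel-transposed kernel, so no
scatter (col2im) loop is ever needed for stride-1 'same' convolutions.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import as_strided

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus the closure that backpropagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):   # numpy scalar: keep its dtype
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    """Wrap as Tensor; floating arrays keep their dtype, everything else
    (ints, python scalars) becomes float32 so float32 graphs stay float32."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    elif isinstance(x, float):
        arr = arr.astype(np.float32)
    return Tensor(arr)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad],
                  backward=backward if req else None)


# -- arithmetic ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** exponent

    def backward(g):
        if a.requires_grad:
            a._accum(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    """Batched matmul with numpy broadcasting over leading axes."""
    a, b = astensor(a), astensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# -- nonlinearities -----------------------------------------------------------

def relu(a) -> Tensor:
    a = astensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accum(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def exp(a) -> Tensor:
    a = astensor(a)
    e = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * e)

    return _make(e, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(out_data, (a,), backward)


def softmax(a, axis=-1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

    return _make(s, (a,), backward)


def log_softmax(a, axis=-1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    s = np.exp(out_data)

    def backward(g):
        if a.requires_grad:
            a._accum(g - s * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


# -- reductions / shaping -----------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def concat(tensors, axis=1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _make(out_data, tensors, backward)


# -- convolution and friends --------------------------------------------------

def _im2col(x: np.ndarray, k: int, dilation: int, padding: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) stride-1 'same'-style patch matrix."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    ho = hp - dilation * (k - 1)
    wo = wp - dilation * (k - 1)
    s0, s1, s2, s3 = x.strides
    win = as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2 * dilation, s3 * dilation, s2, s3),
        writeable=False,
    )
    return np.ascontiguousarray(win).reshape(n, c * k * k, ho * wo), (ho, wo)


def _conv2d_raw(x: np.ndarray, w: np.ndarray, dilation: int, padding: int) -> np.ndarray:
    """Forward-only stride-1 convolution (cross-correlation), NCHW."""
    n = x.shape[0]
    co, ci, k, _ = w.shape
    if k == 1 and padding == 0:
        # plain channel mixing
        xf = x.reshape(n, ci, -1)
        out = np.matmul(w.reshape(co, ci), xf)
        return out.reshape(n, co, x.shape[2], x.shape[3])
    cols, (ho, wo) = _im2col(x, k, dilation, padding)
    out = np.matmul(w.reshape(co, -1), cols)
    return out.reshape(n, co, ho, wo)


def conv2d(x, w, b=None, dilation: int = 1, padding: int | None = None) -> Tensor:
    """Stride-1 2-D convolution; default padding keeps spatial size ('same')."""
    x, w = astensor(x), astensor(w)
    co, ci, k, _ = w.data.shape
    if padding is None:
        padding = dilation * (k - 1) // 2
    out_data = _conv2d_raw(x.data, w.data, dilation, padding)
    if b is not None:
        b = astensor(b)
        out_data = out_data + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        n = x.data.shape[0]
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            if k == 1 and padding == 0:
                gf = g.reshape(n, co, -1)
                xf = x.data.reshape(n, ci, -1)
                gw = np.einsum("nol,ncl->oc", gf, xf, optimize=True).reshape(w.data.shape)
            else:
                cols, _ = _im2col(x.data, k, dilation, padding)
                gf = g.reshape(n, co, -1)
                gw = np.einsum("nol,nkl->ok", gf, cols, optimize=True).reshape(w.data.shape)
            w._accum(gw.astype(w.data.dtype, copy=False))
        if x.requires_grad:
            # grad wrt input = conv of g with flipped, channel-swapped kernel
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            pad_back = dilation * (k - 1) - padding
            gx = _conv2d_raw(g, np.ascontiguousarray(w_flip), dilation, pad_back)
            x._accum(gx.astype(x.data.dtype, copy=False))

    return _make(out_data, parents, backward)


def maxpool2x2(x) -> Tensor:
    x = astensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(gx)

    return _make(out_data, (x,), backward)


def avgpool2x2(x) -> Tensor:
    x = astensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accum(gx)

    return _make(out_data, (x,), backward)


def _bilinear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic 1-D linear interpolation matrix (half-pixel centers)."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        a[i, lo_c] += 1.0 - t
        a[i, hi_c] += t
    return a


_BILINEAR_CACHE: dict = {}


def upsample_bilinear(x, size) -> Tensor:
    """Bilinear resize of (N,C,H,W) to spatial `size` (half-pixel alignment)."""
    x = astensor(x)
    n, c, h, w = x.data.shape
    ho, wo = size
    key = (ho, h, wo, w, x.data.dtype.str)
    if key not in _BILINEAR_CACHE:
        _BILINEAR_CACHE[key] = (
            _bilinear_matrix(ho, h, x.data.dtype),
            _bilinear_matrix(wo, w, x.data.dtype),
        )
    ah, aw = _BILINEAR_CACHE[key]
    out_data = np.einsum("ij,ncjk,lk->ncil", ah, x.data, aw, optimize=True)

    def backward(g):
        if x.requires_grad:
            gx = np.einsum("ij,ncil,lk->ncjk", ah, g, aw, optimize=True)
            x._accum(gx.astype(x.data.dtype, copy=False))

    return _make(out_data, (x,), backward)


def batchnorm2d(x, gamma, beta, running_mean, running_var, training: bool,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N,H,W) per channel.

    `running_mean`/`running_var` are plain mutable numpy buffers updated
    in-place when `training` is True.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    c = x.data.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(gshape)) * inv_std.reshape(gshape)
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data.reshape(gshape) * inv_std.reshape(gshape)
            if training:
                g_mean = g.mean(axis=(0, 2, 3), keepdims=True)
                gx_mean = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accum(gs * (g - g_mean - xhat * gx_mean))
            else:
                x._accum(gs * g)

    return _make(out_data, (x, gamma, beta), backward)
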