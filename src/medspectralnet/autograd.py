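"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the tensor primitives the network needs: broadcasting
arithmetic, matmul, 2-D (grouped) convolution via im2col, max pooling,
axis reductions, reshape/slice/concat, the activations used by the model,
and softmax / log-softmax.  Gradients are accumulated on every node of the
graph (no retain-graph machinery), which is what the Grad-CAM hooks rely on.

Convolution forward/backward are expressed as dense matrix products so the
heavy lifting stays inside BLAS; the col2im scatter is unrolled over the
k*k kernel taps, which keeps it vectorised for the strided case too.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor", "Parameter", "constant",
    "add", "sub", "mul", "neg", "pow_", "exp", "log", "matmul",
    "relu", "sigmoid", "gelu", "softmax", "log_softmax",
    "sum_", "mean", "reshape", "concat", "getitem", "select_rows",
    "conv2d", "maxpool2d", "pad_bottom_right", "linear",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return self.data.item()

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor; defaults to d(self)/d(self)=1 for scalars."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))

        _accum(self, grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return neg(self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / other)

    def __pow__(self, exponent):
        return pow_(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


class Parameter(Tensor):
    """A tensor that is part of a model's trainable state."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def constant(data, dtype=None):
    arr = np.asarray(data, dtype=dtype)
    return Tensor(arr)


# -- plumbing ---------------------------------------------------------------

def _as_tensor(x, like=None):
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def _accum(t, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- arithmetic -------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a, b if isinstance(b, Tensor) else None), _as_tensor(b, a if isinstance(a, Tensor) else None)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _as_tensor(a, b if isinstance(b, Tensor) else None), _as_tensor(b, a if isinstance(a, Tensor) else None)
    out_data = a.data - b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a, b if isinstance(b, Tensor) else None), _as_tensor(b, a if isinstance(a, Tensor) else None)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward)


def pow_(a, exponent):
    out_data = a.data ** exponent

    def backward(g):
        _accum(a, g * exponent * a.data ** (exponent - 1))

    return _make(out_data, (a,), backward)


def exp(a):
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def matmul(a, b):
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# -- activations ------------------------------------------------------------

def relu(a):
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a):
    from scipy.special import expit
    out_data = expit(a.data)

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a):
    """Exact GELU: x * Phi(x) with Phi the standard normal CDF."""
    cdf = 0.5 * (1.0 + erf(a.data / _SQRT2))
    out_data = a.data * cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data * a.data)
        _accum(a, g * (cdf + a.data * pdf))

    return _make((out_data).astype(a.data.dtype), (a,), backward)


def softmax(a, axis=-1):
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), backward)


def log_softmax(a, axis=-1):
    m = a.data.max(axis=axis, keepdims=True)
    shifted = a.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    sm = np.exp(out_data)

    def backward(g):
        _accum(a, g - sm * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


# -- shape ops ---------------------------------------------------------------

def reshape(a, shape):
    old_shape = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(old_shape))

    return _make(out_data, (a,), backward)


def sum_(a, axis=None, keepdims=False):
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            g = np.expand_dims(g, tuple(sorted(axes)))
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = 1
        for ax in axes:
            count *= a.data.shape[ax]
    return mul(sum_(a, axis, keepdims), 1.0 / count)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(out_data, tuple(tensors), backward)


def getitem(a, idx):
    """Basic (slice/int) indexing with gradient support."""
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _accum(a, full)

    return _make(out_data, (a,), backward)


def select_rows(a, row_idx):
    """out[i] = a[i, row_idx[i]] — label gather for cross-entropy."""
    n = a.data.shape[0]
    ar = np.arange(n)
    out_data = a.data[ar, row_idx]

    def backward(g):
        full = np.zeros_like(a.data)
        full[ar, row_idx] = g
        _accum(a, full)

    return _make(out_data, (a,), backward)


def linear(x, weight, bias=None):
    """x (B, I) @ weight (O, I)^T + bias (O,)."""
    out_data = x.data @ weight.data.T
    if bias is not None:
        out_data = out_data + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        _accum(x, g @ weight.data)
        _accum(weight, g.T @ x.data)
        if bias is not None:
            _accum(bias, g.sum(axis=0))

    return _make(out_data, parents, backward)


# -- padding ------------------------------------------------------------------

def _pad_indices(length, pad):
    """Bottom/right pad index map: reflect where possible, edge otherwise."""
    idx = list(range(length))
    if pad > 0:
        if length > 1:
            # mirror without repeating the border sample; wrap if pad is long
            mirror = list(range(length - 2, -1, -1)) + list(range(1, length))
            while len(mirror) < pad:
                mirror = mirror + mirror
            idx += mirror[:pad]
        else:
            idx += [0] * pad
    return np.asarray(idx, dtype=np.intp)


def pad_bottom_right(a, pad_h, pad_w):
    """Reflection-pad the last two axes on the bottom/right only."""
    if pad_h == 0 and pad_w == 0:
        return a
    H, W = a.data.shape[-2:]
    ih = _pad_indices(H, pad_h)
    iw = _pad_indices(W, pad_w)
    out_data = a.data[..., ih[:, None], iw[None, :]]

    # scatter matrices: S_h[i, I] = 1 where padded row I reads source row i
    sh = np.zeros((H, H + pad_h), dtype=a.data.dtype)
    sh[ih, np.arange(H + pad_h)] = 1
    sw = np.zeros((W, W + pad_w), dtype=a.data.dtype)
    sw[iw, np.arange(W + pad_w)] = 1

    def backward(g):
        _accum(a, sh @ g @ sw.T)

    return _make(out_data, (a,), backward)


# -- convolution / pooling -----------------------------------------------------

def _im2col_view(xp, kh, kw, sh, sw):
    B, C, Hp, Wp = xp.shape
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (B, C, kh, kw, Ho, Wo),
        (s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw),
    )
    return cols, Ho, Wo


def _col2im(dcols, xp_shape, kh, kw, sh, sw, Ho, Wo):
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += dcols[:, :, i, j]
    return dxp


# active MAC recorder, set by the profiler module
_MAC_TRACE = None


def _record_macs(name, macs):
    if _MAC_TRACE is not None:
        _MAC_TRACE.append((name, int(macs)))


def conv2d(x, weight, bias=None, stride=1, padding=0, groups=1, op_name="conv2d"):
    """2-D cross-correlation; weight (Co, Ci/groups, kh, kw), x (B, Ci, H, W)."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    B, C, H, W = x.data.shape
    Co, Cig, kh, kw = weight.data.shape
    if C != Cig * groups:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cig * groups}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols, Ho, Wo = _im2col_view(xp, kh, kw, sh, sw)
    _record_macs(op_name, Co * Cig * kh * kw * Ho * Wo)

    if groups == 1:
        cols2 = np.ascontiguousarray(cols.transpose(1, 2, 3, 0, 4, 5)).reshape(C * kh * kw, B * Ho * Wo)
        wmat = weight.data.reshape(Co, C * kh * kw)
        out = (wmat @ cols2).reshape(Co, B, Ho, Wo).transpose(1, 0, 2, 3)
    elif groups == C and Co == C:
        wd = weight.data.reshape(C, kh, kw)
        out = np.einsum("bcijhw,cij->bchw", cols, wd, optimize=True)
    else:
        out = np.empty((B, Co, Ho, Wo), dtype=x.data.dtype)
        cg, cog = C // groups, Co // groups
        for g_i in range(groups):
            sub = cols[:, g_i * cg:(g_i + 1) * cg]
            sub2 = np.ascontiguousarray(sub.transpose(1, 2, 3, 0, 4, 5)).reshape(cg * kh * kw, B * Ho * Wo)
            wmat = weight.data[g_i * cog:(g_i + 1) * cog].reshape(cog, cg * kh * kw)
            out[:, g_i * cog:(g_i + 1) * cog] = (wmat @ sub2).reshape(cog, B, Ho, Wo).transpose(1, 0, 2, 3)

    out = np.ascontiguousarray(out)
    if bias is not None:
        out += bias.data.reshape(1, Co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g = np.ascontiguousarray(g)
        if bias is not None:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if groups == 1:
            g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(Co, B * Ho * Wo)
            cols2b = np.ascontiguousarray(cols.transpose(1, 2, 3, 0, 4, 5)).reshape(C * kh * kw, B * Ho * Wo)
            _accum(weight, (g2 @ cols2b.T).reshape(weight.data.shape))
            if x.requires_grad:
                dcols = (weight.data.reshape(Co, C * kh * kw).T @ g2)
                dcols = dcols.reshape(C, kh, kw, B, Ho, Wo).transpose(3, 0, 1, 2, 4, 5)
                dxp = _col2im(dcols, xp.shape, kh, kw, sh, sw, Ho, Wo)
                _accum(x, dxp[:, :, ph:ph + H, pw:pw + W])
        elif groups == C and Co == C:
            _accum(weight, np.einsum("bchw,bcijhw->cij", g, cols, optimize=True).reshape(weight.data.shape))
            if x.requires_grad:
                dcols = np.einsum("bchw,cij->bcijhw", g, weight.data.reshape(C, kh, kw), optimize=True)
                dxp = _col2im(dcols, xp.shape, kh, kw, sh, sw, Ho, Wo)
                _accum(x, dxp[:, :, ph:ph + H, pw:pw + W])
        else:
            dw = np.zeros_like(weight.data)
            dxp = np.zeros(xp.shape, dtype=g.dtype)
            cg, cog = C // groups, Co // groups
            for g_i in range(groups):
                gs = np.ascontiguousarray(g[:, g_i * cog:(g_i + 1) * cog].transpose(1, 0, 2, 3)).reshape(cog, -1)
                sub = cols[:, g_i * cg:(g_i + 1) * cg]
                sub2 = np.ascontiguousarray(sub.transpose(1, 2, 3, 0, 4, 5)).reshape(cg * kh * kw, -1)
                dw[g_i * cog:(g_i + 1) * cog] = (gs @ sub2.T).reshape(cog, cg, kh, kw)
                dcols = (weight.data[g_i * cog:(g_i + 1) * cog].reshape(cog, -1).T @ gs)
                dcols = dcols.reshape(cg, kh, kw, B, Ho, Wo).transpose(3, 0, 1, 2, 4, 5)
                dxp[:, g_i * cg:(g_i + 1) * cg] += _col2im(
                    dcols, (B, cg, xp.shape[2], xp.shape[3]), kh, kw, sh, sw, Ho, Wo)
            _accum(weight, dw)
            if x.requires_grad:
                _accum(x, dxp[:, :, ph:ph + H, pw:pw + W])

    return _make(out, parents, backward)


def maxpool2d(x, kernel_size, stride=None, padding=0):
    k = kernel_size
    s = stride if stride is not None else k
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    cols, Ho, Wo = _im2col_view(xp, k, k, s, s)
    flat = cols.reshape(B, C, k * k, Ho, Wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        dxp = np.zeros(xp.shape, dtype=g.dtype)
        for p in range(k * k):
            i, j = divmod(p, k)
            contrib = g * (arg == p)
            dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += contrib
        if padding:
            dxp = dxp[:, :, padding:padding + H, padding:padding + W]
        _accum(x, dxp)

    return _make(np.ascontiguousarray(out), (x,), backward)
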