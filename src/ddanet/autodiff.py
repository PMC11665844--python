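"""Reverse-mode automatic differentiation on NumPy arrays.

A compact define-by-run autodiff engine sized for 2-D convolutional
segmentation networks: :class:`Tensor` wraps an ``ndarray``, records the
operations applied to it, and :meth:`Tensor.backward` accumulates gradients
by reverse topological traversal of the recorded graph.

Only the primitives this model family needs are provided — elementwise
arithmetic with broadcasting, matmul, reductions, the logistic/ReLU/softmax
nonlinearities, 2-D convolution with stride/padding/dilation (im2col),
max-pooling, and ×2 bilinear upsampling.  Every primitive's gradient is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "conv2d", "max_pool2d", "upsample_bilinear_x2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(value) -> np.ndarray:
    if isinstance(value, np.ndarray) and value.dtype in (np.float64, np.float32):
        return value
    arr = np.asarray(value)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    return arr


class Tensor:
    """An ``ndarray`` with a gradient and a backward graph edge."""

    # Make NumPy defer to our reflected operators (ndarray * Tensor etc.).
    __array_ufunc__ = None

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(value, like: np.dtype | None = None) -> "Tensor":
        if isinstance(value, Tensor):
            return value
        if like is not None and isinstance(value, (int, float)):
            # keep python scalars in the partner's dtype (avoid f32→f64 creep)
            return Tensor(np.asarray(value, dtype=like))
        return Tensor(value)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, copy=True)
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None) -> None:
        """Accumulate gradients of `self` w.r.t. every reachable leaf."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big models
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other, self.data.dtype)
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._node(out_data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._lift(other, self.data.dtype)
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other, self.data.dtype) + (-self)

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other, self.data.dtype)
        out_data = a.data / b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._node(out_data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other, self.data.dtype) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor._node(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = np.matmul(a.data, b.data)

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._node(out_data, (a, b), backward)

    # -- shape ----------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def backward(g):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor._node(out_data, (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inverse = np.argsort(axes)
        out_data = a.data.transpose(axes)

        def backward(g):
            a._accumulate(g.transpose(inverse))

        return Tensor._node(out_data, (a,), backward)

    @property
    def T(self):
        return self.transpose()

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._node(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; ties route the gradient to the first hit."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            grad = np.zeros_like(a.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), g, axis=axis)
            a._accumulate(grad)

        return Tensor._node(out_data, (a,), backward)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        out_data = a.data * mask

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._node(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        # numerically stable logistic: exp only ever sees non-positive input
        pos = a.data >= 0
        e = np.exp(np.where(pos, -a.data, a.data))
        out_data = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (a,), backward)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._node(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._node(out_data, (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where the input is inside."""
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._node(out_data, (a,), backward)

    def softmax(self, axis: int = -1):
        # shift-invariance of softmax makes the detached max gradient-exact
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


# -- multi-input / structured primitives --------------------------------------


def concatenate(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accumulate(g[tuple(sl)])

    return Tensor._node(out_data, parts, backward)


_COL_INDEX_CACHE: dict[tuple, tuple] = {}


def _im2col_indices(C, kh, kw, ho, wo, stride, dilation):
    key = (C, kh, kw, ho, wo, stride, dilation)
    cached = _COL_INDEX_CACHE.get(key)
    if cached is None:
        i0 = np.tile(np.repeat(np.arange(kh) * dilation, kw), C)
        j0 = np.tile(np.tile(np.arange(kw) * dilation, kh), C)
        i1 = stride * np.repeat(np.arange(ho), wo)
        j1 = stride * np.tile(np.arange(wo), ho)
        rows = i0[:, None] + i1[None, :]          # (C*kh*kw, ho*wo)
        cols = j0[:, None] + j1[None, :]
        chan = np.repeat(np.arange(C), kh * kw)[:, None]
        cached = (chan, rows, cols)
        _COL_INDEX_CACHE[key] = cached
    return cached


def _col2im(gcols: np.ndarray, chan, rows, cols, n, c, hp, wp) -> np.ndarray:
    """Adjoint of the im2col gather: scatter-add patch gradients back."""
    flat = ((chan * hp + rows) * wp + cols).ravel()       # (K*P,)
    per_image = c * hp * wp
    out = np.empty((n, per_image), dtype=gcols.dtype)
    for b in range(n):  # bincount per image beats ufunc.at by a wide margin
        out[b] = np.bincount(flat, weights=gcols[b].ravel(), minlength=per_image)
    return out.reshape(n, c, hp, wp)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation on NCHW input, via im2col + matmul."""
    x = Tensor._lift(x)
    weight = Tensor._lift(weight)
    n, c, h, w = x.shape
    o, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"conv2d: input has {c} channels but weight expects {cw}")
    ho = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    wo = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: kernel does not fit input of size {h}x{w}")
    if kh == kw == 1 and padding == 0:
        return _conv1x1(x, weight, bias, stride, n, c, h, w, o)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    chan, rows, cols = _im2col_indices(c, kh, kw, ho, wo, stride, dilation)
    patches = xp[:, chan, rows, cols]              # (N, C*kh*kw, ho*wo)
    w2 = weight.data.reshape(o, -1)
    out_data = np.matmul(w2, patches).reshape(n, o, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(n, o, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("nop,nkp->ok", g2, patches, optimize=True)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g2)            # (N, C*kh*kw, ho*wo)
            gxp = _col2im(gcols, chan, rows, cols, n, c,
                          h + 2 * padding, w + 2 * padding)
            gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
            x._accumulate(gx)

    return Tensor._node(out_data, parents, backward)


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor | None,
             stride: int, n: int, c: int, h: int, w: int, o: int) -> Tensor:
    """Pointwise convolution as a plain channel matmul (no im2col)."""
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    ho, wo = xs.shape[2], xs.shape[3]
    flat = xs.reshape(n, c, ho * wo)
    w2 = weight.data.reshape(o, c)
    out_data = np.matmul(w2, flat).reshape(n, o, ho, wo)
    if bias is not None:
        out_data += bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(n, o, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("nop,ncp->oc", g2, flat, optimize=True)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gx_s = np.matmul(w2.T, g2).reshape(n, c, ho, wo)
            if stride > 1:
                gx = np.zeros((n, c, h, w), dtype=g.dtype)
                gx[:, :, ::stride, ::stride] = gx_s
            else:
                gx = gx_s
            x._accumulate(gx)

    return Tensor._node(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling on NCHW input; padded entries never win the max."""
    x = Tensor._lift(x)
    stride = kernel if stride is None else stride
    n, c, h, w = x.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    chan, rows, cols = _im2col_indices(c, kernel, kernel, ho, wo, stride, 1)
    patches = xp[:, chan, rows, cols].reshape(n, c, kernel * kernel, ho * wo)
    idx = np.argmax(patches, axis=2)               # first index wins ties
    out_data = np.take_along_axis(patches, idx[:, :, None, :], axis=2)
    out_data = out_data[:, :, 0, :].reshape(n, c, ho, wo)

    def backward(g):
        gpatch = np.zeros((n, c, kernel * kernel, ho * wo), dtype=g.dtype)
        np.put_along_axis(gpatch, idx[:, :, None, :],
                          g.reshape(n, c, 1, ho * wo), axis=2)
        gpatch = gpatch.reshape(n, c * kernel * kernel, ho * wo)
        gxp = _col2im(gpatch, chan, rows, cols, n, c,
                      h + 2 * padding, w + 2 * padding)
        gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
        x._accumulate(gx)

    return Tensor._node(out_data, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float,
                 ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalisation over the (N, H, W) axes.

    Returns ``(gamma·(x − μ)/√(σ² + eps) + beta, μ, σ²)`` with batch
    moments; the hand-derived backward matches the composed-ops gradient
    but builds a single graph node.
    """
    x = Tensor._lift(x)
    n, c, h, w = x.shape
    m = n * h * w
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    var = np.square(x.data - mu).mean(axis=(0, 2, 3), keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    g4 = gamma.data.reshape(1, c, 1, 1)
    out_data = g4 * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        gxh_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        if gamma.requires_grad:
            gamma._accumulate(gxh_sum.reshape(c))
        if x.requires_grad:
            g_sum = g.sum(axis=(0, 2, 3), keepdims=True)
            dx = (g4 * inv_std) * (g - g_sum / m - xhat * (gxh_sum / m))
            x._accumulate(dx)

    out = Tensor._node(out_data, (x, gamma, beta), backward)
    return out, mu.reshape(c), var.reshape(c)


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """Dense (2n × n) ×2 bilinear interpolation operator (half-pixel centres)."""
    mat = _UPSAMPLE_CACHE.get(n)
    if mat is None:
        src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        src = np.clip(src, 0.0, n - 1.0)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = src - lo
        mat = np.zeros((2 * n, n))
        np.add.at(mat, (np.arange(2 * n), lo), 1.0 - frac)
        np.add.at(mat, (np.arange(2 * n), hi), frac)
        _UPSAMPLE_CACHE[n] = mat
    return mat


def upsample_bilinear_x2(x: Tensor) -> Tensor:
    """Double both spatial dimensions of an NCHW tensor by bilinear interpolation."""
    x = Tensor._lift(x)
    n, c, h, w = x.shape
    wh = _upsample_matrix(h).astype(x.dtype)
    ww = _upsample_matrix(w).astype(x.dtype)
    out_data = np.matmul(np.matmul(wh, x.data), ww.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(wh.T, g), ww))

    return Tensor._node(out_data, (x,), backward)
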