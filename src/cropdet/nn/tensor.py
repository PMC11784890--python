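"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and records the backward rule of the operation that produced it.
It supports exactly the operations the detector needs — elementwise
arithmetic and transcendentals, broadcasting, reductions, matmul, 2-D
convolution and pooling — and nothing more.  Gradients are accumulated in
``float64`` or ``float32`` according to the data dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor", "set_default_dtype",
    "exp", "log", "sqrt", "sin", "cos", "arcsin", "arctan", "absolute",
    "maximum", "minimum", "clip", "where", "sigmoid", "silu", "relu",
    "tanh", "softmax", "concatenate", "stack", "pad2d",
    "conv2d", "avg_pool2d", "max_pool2d", "upsample2x", "pad2d_replicate",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype):
    """Set the dtype used for tensors created from Python scalars/lists.

    float32 roughly halves CPU training cost; float64 (the default) is used
    for all exactness-sensitive arithmetic.  Arrays passed in with an
    explicit float dtype always keep it.
    """
    global _DEFAULT_DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE if not isinstance(data, np.ndarray) else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---- factory helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in out._parents)
        if out.requires_grad:
            out._backward = backward
        return out

    # ---- basic protocol --------------------------------------------------
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

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # ---- autograd --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)
        # topological order of the tape
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads eagerly except leaves
                if node._parents:
                    node.grad = None

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad and not self._parents:
            return
        g = _unbroadcast(grad, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g)
                other._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g * other.data)
                other._accum(g * self.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g / other.data)
                other._accum(-g * self.data / (other.data ** 2))
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent):
        if isinstance(exponent, Tensor):
            exponent = exponent.data
        exponent = np.asarray(exponent, dtype=self.data.dtype)
        out = Tensor._make(self.data ** exponent, (self,), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g * exponent * self.data ** (exponent - 1))
            out._backward = backward
        return out

    # comparisons operate on data and return plain arrays (non-differentiable)
    def __lt__(self, other):
        return self.data < (other.data if isinstance(other, Tensor) else other)

    def __gt__(self, other):
        return self.data > (other.data if isinstance(other, Tensor) else other)

    def __le__(self, other):
        return self.data <= (other.data if isinstance(other, Tensor) else other)

    def __ge__(self, other):
        return self.data >= (other.data if isinstance(other, Tensor) else other)

    # ---- shaping ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)
        if out.requires_grad:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = backward
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor._make(out_data, (self,), None)
        if out.requires_grad:
            def backward(g):
                expanded = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
                gg = g if keepdims or axis is None else np.expand_dims(g, axis)
                mask = (self.data == expanded)
                # split gradient between ties
                counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
                self._accum(mask * gg / counts)
            out._backward = backward
        return out

    def matmul(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                a, b = self.data, other.data
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accum(ga)
                other._accum(gb)
            out._backward = backward
        return out

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# dispatching elementwise functions: work on Tensor or ndarray alike
# ---------------------------------------------------------------------------

def _unary(x, fn, dfn):
    if isinstance(x, Tensor):
        out = Tensor._make(fn(x.data), (x,), None)
        if out.requires_grad:
            out._backward = lambda g: x._accum(g * dfn(x.data, out.data))
        return out
    return fn(np.asarray(x, dtype=float))


def exp(x):
    return _unary(x, np.exp, lambda d, o: o)


def log(x):
    return _unary(x, np.log, lambda d, o: 1.0 / d)


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, o: 0.5 / np.maximum(o, 1e-300))


def sin(x):
    return _unary(x, np.sin, lambda d, o: np.cos(d))


def cos(x):
    return _unary(x, np.cos, lambda d, o: -np.sin(d))


def arcsin(x):
    return _unary(x, np.arcsin, lambda d, o: 1.0 / np.sqrt(np.maximum(1.0 - d * d, 1e-12)))


def arctan(x):
    return _unary(x, np.arctan, lambda d, o: 1.0 / (1.0 + d * d))


def absolute(x):
    return _unary(x, np.abs, lambda d, o: np.sign(d))


def tanh(x):
    return _unary(x, np.tanh, lambda d, o: 1.0 - o * o)


def sigmoid(x):
    def fn(d):
        return np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500))),
                        np.exp(np.clip(d, -500, 500)) / (1.0 + np.exp(np.clip(d, -500, 500))))
    return _unary(x, fn, lambda d, o: o * (1.0 - o))


def silu(x):
    s = sigmoid(x)
    return x * s


def relu(x):
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, o: (d > 0).astype(d.dtype))


def maximum(a, b):
    """Elementwise max; subgradient splits evenly at ties."""
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.maximum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor._make(np.maximum(a.data, b.data), (a, b), None)
    if out.requires_grad:
        def backward(g):
            ga = np.where(a.data > b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))
            a._accum(g * ga)
            b._accum(g * (1.0 - ga))
        out._backward = backward
    return out


def minimum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.minimum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor._make(np.minimum(a.data, b.data), (a, b), None)
    if out.requires_grad:
        def backward(g):
            ga = np.where(a.data < b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))
            a._accum(g * ga)
            b._accum(g * (1.0 - ga))
        out._backward = backward
    return out


def clip(x, lo, hi):
    return minimum(maximum(x, lo), hi)


def where(cond, a, b):
    cond = cond.data if isinstance(cond, Tensor) else np.asarray(cond)
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.where(cond, a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor._make(np.where(cond, a.data, b.data), (a, b), None)
    if out.requires_grad:
        def backward(g):
            a._accum(g * cond)
            b._accum(g * (~cond if cond.dtype == bool else 1 - cond))
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached max: stable
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, None)
    if out.requires_grad:
        def backward(g):
            for i, t in enumerate(tensors):
                t._accum(np.take(g, i, axis=axis))
        out._backward = backward
    return out


def pad2d(x: Tensor, pad: int, value: float = 0.0) -> Tensor:
    """Constant-pad the two trailing spatial axes of an NCHW tensor."""
    if pad == 0:
        return as_tensor(x)
    x = as_tensor(x)
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    out = Tensor._make(np.pad(x.data, widths, constant_values=value), (x,), None)
    if out.requires_grad:
        def backward(g):
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            x._accum(g[sl])
        out._backward = backward
    return out


def pad2d_replicate(x: Tensor, pad: int) -> Tensor:
    """Edge-replicate padding of the trailing two axes of an NCHW tensor."""
    x = as_tensor(x)
    if pad == 0:
        return x
    h, w = x.data.shape[-2], x.data.shape[-1]
    ri = np.clip(np.arange(-pad, h + pad), 0, h - 1)
    ci = np.clip(np.arange(-pad, w + pad), 0, w - 1)
    out = Tensor._make(x.data[..., ri[:, None], ci[None, :]], (x,), None)
    if out.requires_grad:
        def backward(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, (Ellipsis, ri[:, None], ci[None, :]), g)
            x._accum(gx)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# 2-D convolution and pooling (NCHW)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) for a pre-padded input."""
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (N,C,OH,OW,kh,kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _dilate(g: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return g
    n, c, h, w = g.shape
    out = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=g.dtype)
    out[:, :, ::stride, ::stride] = g
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int, groups: int):
    n, cin, _, _ = x.shape
    cout, cin_g, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    if groups == 1:
        cols, oh, ow = _im2col(x, kh, kw, stride)
        out = np.einsum("ok,nkl->nol", w.reshape(cout, -1), cols, optimize=True)
        return out.reshape(n, cout, oh, ow), cols
    outs, col_list = [], []
    og = cout // groups
    for g in range(groups):
        xs = x[:, g * cin_g:(g + 1) * cin_g]
        cols, oh, ow = _im2col(xs, kh, kw, stride)
        wg = w[g * og:(g + 1) * og].reshape(og, -1)
        outs.append(np.einsum("ok,nkl->nol", wg, cols, optimize=True).reshape(n, og, oh, ow))
        col_list.append(cols)
    return np.concatenate(outs, axis=1), col_list


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """Cross-correlation in NCHW layout, the deep-learning convention."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    out_data, cols = _conv_forward(x.data, weight.data, stride, padding, groups)
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        parents.append(bias)
    out = Tensor._make(out_data, parents, None)
    if out.requires_grad:
        cout, cin_g, kh, kw = weight.data.shape
        og = cout // groups

        def backward(g):
            n, _, oh, ow = g.shape
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            gflat = g.reshape(n, cout, oh * ow)
            # weight gradient from cached columns
            if groups == 1:
                gw = np.einsum("nol,nkl->ok", gflat, cols, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
            else:
                gws = []
                for gi in range(groups):
                    gws.append(np.einsum(
                        "nol,nkl->ok", gflat[:, gi * og:(gi + 1) * og], cols[gi],
                        optimize=True).reshape(og, cin_g, kh, kw))
                weight._accum(np.concatenate(gws, axis=0))
            # input gradient = conv of dilated g with the flipped kernel
            gd = _dilate(g, stride)
            wflip = weight.data[:, :, ::-1, ::-1]
            if groups == 1:
                wt = wflip.transpose(1, 0, 2, 3)          # (Cin, Cout, kh, kw)
                gx, _ = _conv_forward(gd, wt, 1, kh - 1, 1)
            else:
                gx_parts = []
                for gi in range(groups):
                    wt = wflip[gi * og:(gi + 1) * og].transpose(1, 0, 2, 3)
                    part, _ = _conv_forward(gd[:, gi * og:(gi + 1) * og], wt, 1, kh - 1, 1)
                    gx_parts.append(part)
                gx = np.concatenate(gx_parts, axis=1)
            # crop padding back off, and right/bottom overhang from stride
            h_in, w_in = x.data.shape[2], x.data.shape[3]
            gx = gx[:, :, padding:padding + h_in, padding:padding + w_in]
            if gx.shape[2] < h_in or gx.shape[3] < w_in:
                gx = np.pad(gx, ((0, 0), (0, 0),
                                 (0, h_in - gx.shape[2]), (0, w_in - gx.shape[3])))
            x._accum(gx)
        out._backward = backward
    return out


def avg_pool2d(x, kernel: int, stride: int = 1, padding: int = 0):
    """Mean pooling; the count includes zero padding (matches conv fusion)."""
    x = as_tensor(x)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    n, c, h, w = xp.shape
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    out_data = win.mean(axis=(-1, -2))
    out = Tensor._make(out_data, (x,), None)
    if out.requires_grad:
        def backward(g):
            gd = _dilate(g, stride) / (kernel * kernel)
            # correlate with a ones kernel: every input cell collects the
            # windows that contained it
            gp = np.pad(gd, ((0, 0), (0, 0), (kernel - 1, kernel - 1), (kernel - 1, kernel - 1)))
            wv = np.lib.stride_tricks.sliding_window_view(gp, (kernel, kernel), axis=(2, 3))
            gx = wv.sum(axis=(-1, -2))
            h_in, w_in = x.data.shape[2], x.data.shape[3]
            gx = gx[:, :, padding:padding + h_in, padding:padding + w_in]
            if gx.shape[2] < h_in or gx.shape[3] < w_in:
                gx = np.pad(gx, ((0, 0), (0, 0),
                                 (0, h_in - gx.shape[2]), (0, w_in - gx.shape[3])))
            x._accum(gx)
        out._backward = backward
    return out


def max_pool2d(x, kernel: int, stride: int = 1, padding: int = 0):
    x = as_tensor(x)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    flat = win.reshape(n, c, oh, ow, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor._make(out_data, (x,), None)
    if out.requires_grad:
        def backward(g):
            gx = np.zeros_like(xp)
            ki, kj = np.unravel_index(arg, (kernel, kernel))
            ii = (np.arange(oh) * stride)[None, None, :, None] + ki
            jj = (np.arange(ow) * stride)[None, None, None, :] + kj
            nn = np.arange(n)[:, None, None, None]
            cc = np.arange(c)[None, :, None, None]
            np.add.at(gx, (nn, cc, ii, jj), g)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)
        out._backward = backward
    return out


def upsample2x(x, mode: str = "nearest"):
    """Double spatial resolution of an NCHW tensor."""
    x = as_tensor(x)
    if mode == "nearest":
        out = Tensor._make(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,), None)
        if out.requires_grad:
            def backward(g):
                n, c, h2, w2 = g.shape
                x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))
            out._backward = backward
        return out
    if mode != "bilinear":
        raise ValueError(f"unknown upsample mode {mode!r}")
    n, c, h, w = x.data.shape
    # align_corners=False sampling: out pixel i maps to source (i+0.5)/2-0.5
    def taps(m):
        src = (np.arange(2 * m) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, m - 1)
        i1 = np.clip(i0 + 1, 0, m - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t = np.where(src < 0, 0.0, np.where(src > m - 1, 1.0, t))
        return i0, i1, t
    r0, r1, tr = taps(h)
    c0, c1, tc = taps(w)
    d = x.data
    top = d[:, :, r0][:, :, :, c0] * ((1 - tr)[:, None] * (1 - tc)[None, :]) \
        + d[:, :, r0][:, :, :, c1] * ((1 - tr)[:, None] * tc[None, :])
    bot = d[:, :, r1][:, :, :, c0] * (tr[:, None] * (1 - tc)[None, :]) \
        + d[:, :, r1][:, :, :, c1] * (tr[:, None] * tc[None, :])
    out = Tensor._make(top + bot, (x,), None)
    if out.requires_grad:
        def backward(g):
            gx = np.zeros_like(x.data)
            w00 = (1 - tr)[:, None] * (1 - tc)[None, :]
            w01 = (1 - tr)[:, None] * tc[None, :]
            w10 = tr[:, None] * (1 - tc)[None, :]
            w11 = tr[:, None] * tc[None, :]
            R0 = r0[:, None]; R1 = r1[:, None]; C0 = c0[None, :]; C1 = c1[None, :]
            np.add.at(gx, (slice(None), slice(None), R0, C0), g * w00)
            np.add.at(gx, (slice(None), slice(None), R0, C1), g * w01)
            np.add.at(gx, (slice(None), slice(None), R1, C0), g * w10)
            np.add.at(gx, (slice(None), slice(None), R1, C1), g * w11)
            x._accum(gx)
        out._backward = backward
    return out
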