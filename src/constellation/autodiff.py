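"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package needs gradients in exactly two places: the differentiable
edge-matching loss optimised by the gradient-descent solver, and the
adversarial training of the convolutional generator.  Both are small,
fixed computation graphs, so a compact tape-based engine is sufficient.

Every function in this module accepts either a :class:`Tensor` or a plain
``numpy`` array; plain arrays fall through to numpy, which lets forward-only
callers (the genetic search evaluates thousands of candidate images and
never needs gradients) share one implementation of the generator math.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "exp", "log", "sqrt", "tanh", "sigmoid", "sin", "cos", "absolute",
    "atan2", "power", "softplus", "leaky_relu", "relu",
    "tensor_sum", "mean", "reshape", "transpose", "concatenate",
    "conv2d", "conv_transpose2d", "bilinear_resize",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    for _ in range(ndim_extra):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100.0  # make ndarray.__mul__ defer to Tensor.__rmul__

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of `self` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- construction helper ----------------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward_fn
        return out

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)
        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(g * b.data)
            if b.requires_grad:
                b._accum(g * a.data)
        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(g / b.data)
            if b.requires_grad:
                b._accum(-g * a.data / (b.data * b.data))
        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                b._accum(np.swapaxes(a.data, -1, -2) @ g)
        return Tensor._make(a.data @ b.data, (a, b), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor._make(a.data[idx], (a,), bw)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def item(self) -> float:
        return float(self.data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions (Tensor or ndarray) ------------------------------

def _unary(x, fn, dfn):
    if not isinstance(x, Tensor):
        return fn(np.asarray(x, dtype=np.float64))
    y = fn(x.data)

    def bw(g):
        if x.requires_grad:
            x._accum(g * dfn(x.data, y))
    return Tensor._make(y, (x,), bw)


def exp(x):
    return _unary(x, np.exp, lambda d, y: y)


def log(x):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def sqrt(x):
    def d(dat, y):
        out = np.zeros_like(y)
        np.divide(0.5, y, out=out, where=y > 0)
        return out
    return _unary(x, np.sqrt, d)


def tanh(x):
    return _unary(x, np.tanh, lambda d, y: 1.0 - y * y)


def sigmoid(x):
    def fn(d):
        return 0.5 * (np.tanh(0.5 * d) + 1.0)  # overflow-safe
    return _unary(x, fn, lambda d, y: y * (1.0 - y))


def sin(x):
    return _unary(x, np.sin, lambda d, y: np.cos(d))


def cos(x):
    return _unary(x, np.cos, lambda d, y: -np.sin(d))


def absolute(x):
    return _unary(x, np.abs, lambda d, y: np.sign(d))


def softplus(x):
    def fn(d):
        return np.logaddexp(0.0, d)
    return _unary(x, fn, lambda d, y: 0.5 * (np.tanh(0.5 * d) + 1.0))


def relu(x):
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, y: (d > 0).astype(np.float64))


def leaky_relu(x, alpha: float = 0.2):
    return _unary(
        x,
        lambda d: np.where(d > 0, d, alpha * d),
        lambda d, y: np.where(d > 0, 1.0, alpha),
    )


def power(x, exponent: float):
    e = float(exponent)
    return _unary(x, lambda d: np.power(d, e), lambda d, y: e * np.power(d, e - 1.0))


def atan2(y, x):
    """Elementwise arctangent of y/x with quadrant handling."""
    if not isinstance(y, Tensor) and not isinstance(x, Tensor):
        return np.arctan2(y, x)
    yt, xt = _as_tensor(y), _as_tensor(x)
    out_data = np.arctan2(yt.data, xt.data)
    denom = yt.data * yt.data + xt.data * xt.data

    def bw(g):
        safe = np.where(denom > 0, denom, 1.0)
        if yt.requires_grad:
            yt._accum(g * xt.data / safe)
        if xt.requires_grad:
            xt._accum(-g * yt.data / safe)
    return Tensor._make(out_data, (yt, xt), bw)


# -- reductions / shape ------------------------------------------------------

def tensor_sum(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis, keepdims=keepdims)
    y = x.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not x.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a % x.data.ndim for a in axes):
                g = np.expand_dims(g, ax)
        x._accum(np.broadcast_to(g, x.data.shape))
    return Tensor._make(y, (x,), bw)


def mean(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.mean(x, axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return tensor_sum(x, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def transpose(x):
    """Swap the trailing two axes."""
    if not isinstance(x, Tensor):
        return np.swapaxes(x, -1, -2)

    def bw(g):
        if x.requires_grad:
            x._accum(np.swapaxes(g, -1, -2))
    return Tensor._make(np.swapaxes(x.data, -1, -2), (x,), bw)


def reshape(x, shape):
    if not isinstance(x, Tensor):
        return np.reshape(x, shape)
    orig = x.data.shape

    def bw(g):
        if x.requires_grad:
            x._accum(np.reshape(g, orig))
    return Tensor._make(x.data.reshape(shape), (x,), bw)


def concatenate(xs, axis=0):
    if not any(isinstance(x, Tensor) for x in xs):
        return np.concatenate(xs, axis=axis)
    ts = [_as_tensor(x) for x in xs]
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(ts, parts):
            if t.requires_grad:
                t._accum(p)
    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


# -- convolution --------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C*k*k, L) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False)
    return patches.reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int):
    """Adjoint of _im2col: scatter-add patches back into an image."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            x[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


def conv2d(x, w, stride: int = 1, pad: int = 0):
    """2-D cross-correlation; x: (N,Cin,H,W), w: (Cout,Cin,k,k)."""
    xt, wt = _as_tensor(x), _as_tensor(w)
    k = wt.data.shape[2]
    cols, (ho, wo) = _im2col(xt.data, k, stride, pad)
    wmat = wt.data.reshape(wt.data.shape[0], -1)
    out = np.einsum("fp,npl->nfl", wmat, cols).reshape(
        xt.data.shape[0], wt.data.shape[0], ho, wo)

    def bw(g):
        gl = g.reshape(g.shape[0], g.shape[1], -1)
        if wt.requires_grad:
            dw = np.einsum("nfl,npl->fp", gl, cols)
            wt._accum(dw.reshape(wt.data.shape))
        if xt.requires_grad:
            dcols = np.einsum("fp,nfl->npl", wmat, gl)
            xt._accum(_col2im(dcols, xt.data.shape, k, stride, pad))
    out_t = Tensor._make(out, (xt, wt), bw)
    return out_t if (xt.requires_grad or wt.requires_grad) else out


def conv_transpose2d(x, w, stride: int = 1, pad: int = 0):
    """Transposed convolution (adjoint of conv2d); x: (N,Cin,H,W), w: (Cin,Cout,k,k)."""
    xt, wt = _as_tensor(x), _as_tensor(w)
    n, cin, h, wdt = xt.data.shape
    cin_w, cout, k, _ = wt.data.shape
    if cin != cin_w:
        raise ValueError("channel mismatch in conv_transpose2d")
    ho = (h - 1) * stride + k - 2 * pad
    wo = (wdt - 1) * stride + k - 2 * pad
    wmat = wt.data.reshape(cin, cout * k * k)
    xl = xt.data.reshape(n, cin, h * wdt)
    cols = np.einsum("cp,ncl->npl", wmat, xl)
    out = _col2im(cols, (n, cout, ho, wo), k, stride, pad)

    def bw(g):
        gcols, _ = _im2col(g, k, stride, pad)
        if xt.requires_grad:
            dx = np.einsum("cp,npl->ncl", wmat, gcols)
            xt._accum(dx.reshape(n, cin, h, wdt))
        if wt.requires_grad:
            dw = np.einsum("ncl,npl->cp", xl, gcols)
            wt._accum(dw.reshape(wt.data.shape))
    out_t = Tensor._make(out, (xt, wt), bw)
    return out_t if (xt.requires_grad or wt.requires_grad) else out


# -- bilinear resize ----------------------------------------------------------

def _resize_weights(n_in: int, n_out: int):
    """Index/weight pairs for 1-D bilinear resampling (half-pixel centres)."""
    scale = n_in / n_out
    centres = (np.arange(n_out) + 0.5) * scale - 0.5
    lo = np.floor(centres).astype(int)
    frac = centres - lo
    lo_c = np.clip(lo, 0, n_in - 1)
    hi_c = np.clip(lo + 1, 0, n_in - 1)
    return lo_c, hi_c, frac


def bilinear_resize(x, out_h: int, out_w: int):
    """Bilinear resample of the trailing two axes (any leading axes)."""
    data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    h, w = data.shape[-2], data.shape[-1]
    ylo, yhi, fy = _resize_weights(h, out_h)
    xlo, xhi, fx = _resize_weights(w, out_w)
    fy = fy.reshape(-1, 1)

    def fwd(d):
        top = d[..., ylo, :]
        bot = d[..., yhi, :]
        rows = top * (1 - fy) + bot * fy
        left = rows[..., :, xlo]
        right = rows[..., :, xhi]
        return left * (1 - fx) + right * fx

    out = fwd(data)
    if not isinstance(x, Tensor):
        return out

    def bw(g):
        if not x.requires_grad:
            return
        grows = np.zeros(g.shape[:-1] + (w,), dtype=np.float64)
        np.add.at(grows, (..., xlo), g * (1 - fx))
        np.add.at(grows, (..., xhi), g * fx)
        gfull = np.zeros(g.shape[:-2] + (h, w), dtype=np.float64)
        ytop = grows * (1 - fy)
        ybot = grows * fy
        np.add.at(gfull, (..., ylo, slice(None)), ytop)
        np.add.at(gfull, (..., yhi, slice(None)), ybot)
        x._accum(gfull)
    return Tensor._make(out, (x,), bw)
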