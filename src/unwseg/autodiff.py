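"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine implements exactly the operator set the segmentation network and
its alignment losses need: broadcasting arithmetic, reductions, matmul,
shape ops, conv/pool/upsample, sigmoid/softmax and a fused cross-entropy.
Tensors deliberately mimic the ndarray method surface (``sum``, ``mean``,
``reshape``, operators) so that the alignment math in :mod:`unwseg.primitives`,
:mod:`unwseg.fca` and :mod:`unwseg.fda` is written once and runs unchanged on
plain arrays (fast, for oracles and analysis) or on tensors (differentiable,
inside training).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concat", "relu", "sigmoid", "softmax",
           "cross_entropy", "conv2d", "conv1x1", "maxpool2x", "upsample2x",
           "channel_max", "stack"]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to Tensor's reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
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
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self):
        return self.data

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            dt = g.dtype if np.issubdtype(g.dtype, np.floating) \
                else np.float64
            self.grad = np.array(g, dtype=dt)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node through the graph."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by DFS
        order, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b,
                       lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents supported")
        out_data = self.data ** p

        def bw(g, a=self, p=p, od=out_data):
            a._accum(g * p * a.data ** (p - 1))
        return Tensor(out_data, parents=(self,), backward=bw)

    def __abs__(self):
        def bw(g, a=self):
            a._accum(g * np.sign(a.data))
        return Tensor(np.abs(self.data), parents=(self,), backward=bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g, a=self, out=out):
            a._accum(g * out)
        return Tensor(out, parents=(self,), backward=bw)

    def log(self):
        def bw(g, a=self):
            a._accum(g / a.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())
        return Tensor(out, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims=False):
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                 axis=axis)
        if not keepdims:
            out = np.squeeze(out, axis=axis)

        def bw(g, a=self, axis=axis, keepdims=keepdims, idx=idx):
            if not keepdims:
                g = np.expand_dims(g, axis)
            ga = np.zeros_like(a.data)
            np.put_along_axis(ga, np.expand_dims(idx, axis), g, axis=axis)
            a._accum(ga)
        return Tensor(out, parents=(self,), backward=bw)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bw(g, a=self, orig=orig):
            a._accum(g.reshape(orig))
        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, a=self, inv=inv):
            a._accum(g.transpose(inv))
        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, key):
        def bw(g, a=self, key=key):
            ga = np.zeros_like(a.data)
            np.add.at(ga, key, g)
            a._accum(ga)
        return Tensor(self.data[key], parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = astensor(other)
        out = self.data @ other.data

        def bw(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))
        return Tensor(out, parents=(self, other), backward=bw)

    def astype(self, dtype):
        orig = self.dtype

        def bw(g, a=self, orig=orig):
            a._accum(g.astype(orig))
        return Tensor(self.data.astype(dtype), parents=(self,), backward=bw)


def astensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Sum a gradient down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, dfa, dfb):
    a, b = astensor(a), astensor(b)
    out = fwd(a.data, b.data)

    def bw(g, a=a, b=b):
        if a.requires_grad:
            a._accum(_unbroadcast(dfa(g, a.data, b.data), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(dfb(g, a.data, b.data), b.shape))
    return Tensor(out, parents=(a, b), backward=bw)


# ---------------------------------------------------------------------------
# neural-network ops
# ---------------------------------------------------------------------------

def relu(x):
    x = astensor(x)
    mask = x.data > 0

    def bw(g, a=x, mask=mask):
        a._accum(g * mask)
    return Tensor(x.data * mask, parents=(x,), backward=bw)


def sigmoid(x):
    x = astensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g, a=x, out=out):
        a._accum(g * out * (1.0 - out))
    return Tensor(out, parents=(x,), backward=bw)


def softmax(x, axis=1):
    """Numerically stable softmax along ``axis``."""
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g, a=x, out=out, axis=axis):
        dot = (g * out).sum(axis=axis, keepdims=True)
        a._accum(out * (g - dot))
    return Tensor(out, parents=(x,), backward=bw)


def cross_entropy(logits, labels):
    """Pixel-averaged CE of raw class logits (N, C, H, W) vs int labels.

    Fused log-softmax + NLL; returns a scalar tensor.
    """
    logits = astensor(logits)
    lab = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n, c = logits.shape[:2]
    onehot = np.moveaxis(np.eye(c, dtype=logits.dtype)[lab], -1, 1)
    npix = lab.size
    loss = -(onehot * logp).sum() / npix

    def bw(g, a=logits, logp=logp, onehot=onehot, npix=npix):
        p = np.exp(logp)
        a._accum(g * (p - onehot) / npix)
    return Tensor(loss, parents=(logits,), backward=bw)


def concat(tensors, axis=1):
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offs = np.cumsum([0] + sizes)

    def bw(g, ts=tensors, offs=offs, axis=axis):
        for t, a, b in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])
    return Tensor(out, parents=tuple(tensors), backward=bw)


def stack(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def bw(g, ts=tensors, axis=axis):
        for i, t in enumerate(ts):
            t._accum(np.take(g, i, axis=axis))
    return Tensor(out, parents=tuple(tensors), backward=bw)


def _im2col(x, k=3, pad=1):
    """(N, C, H, W) -> (N*H*W, k*k*C) patch matrix.

    The patch axis order is (u, v, C) — channels innermost — because the
    copy out of the sliding-window view is then contiguous in C, which is
    several times faster than the channels-outermost layout.
    """
    n, c, h, w = x.shape
    xl = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # NHWC
    xp = np.pad(xl, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * h * w, k * k * c)


def _wmat(w):
    """(Cout, Cin, k, k) kernel -> (k*k*Cin, Cout) matching _im2col order."""
    cout = w.shape[0]
    return np.ascontiguousarray(w.transpose(2, 3, 1, 0).reshape(-1, cout))


def conv2d(x, weight, bias):
    """3x3 same-padding cross-correlation.

    x: (N, Cin, H, W); weight: (Cout, Cin, 3, 3); bias: (Cout,).
    Implemented as im2col + GEMM; the input-gradient is the transposed
    convolution realised with the flipped, channel-swapped kernel.
    """
    x, weight, bias = astensor(x), astensor(weight), astensor(bias)
    n, cin, h, w = x.shape
    cout = weight.shape[0]
    cols = _im2col(x.data)
    out = cols @ _wmat(weight.data)
    out = np.ascontiguousarray(
        out.reshape(n, h, w, cout).transpose(0, 3, 1, 2))
    out += bias.data[None, :, None, None]

    def bw(g, x=x, weight=weight, bias=bias, cols=cols, shape=(n, cin, h, w)):
        n, cin, h, w = shape
        cout = weight.shape[0]
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        if weight.requires_grad:
            gw = (gflat.T @ cols).reshape(cout, 3, 3, cin)
            weight._accum(gw.transpose(0, 3, 1, 2))
        if bias.requires_grad:
            bias._accum(gflat.sum(axis=0))
        if x.requires_grad:
            wt = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gcols = _im2col(np.ascontiguousarray(g))
            gx = gcols @ _wmat(wt)
            x._accum(np.ascontiguousarray(
                gx.reshape(n, h, w, cin).transpose(0, 3, 1, 2)))
    return Tensor(out, parents=(x, weight, bias), backward=bw)


def conv1x1(x, weight, bias=None):
    """Pointwise convolution: weight (Cout, Cin)."""
    x, weight = astensor(x), astensor(weight)
    out = np.einsum("oi,nihw->nohw", weight.data, x.data, optimize=True)
    parents = [x, weight]
    if bias is not None:
        bias = astensor(bias)
        out = out + bias.data[None, :, None, None]
        parents.append(bias)

    def bw(g, x=x, weight=weight, bias=bias):
        if weight.requires_grad:
            weight._accum(np.einsum("nohw,nihw->oi", g, x.data,
                                    optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.einsum("oi,nohw->nihw", weight.data, g,
                               optimize=True))
    return Tensor(out, parents=tuple(parents), backward=bw)


def maxpool2x(x):
    """2x2 max pooling, stride 2; H and W must be even."""
    x = astensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x needs even spatial dims")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    r = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(r, axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bw(g, x=x, idx=idx, shape=(n, c, h, w)):
        n, c, h, w = shape
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(gr)
    return Tensor(out, parents=(x,), backward=bw)


def _interp_matrix(n_out, n_in, dtype=np.float64):
    """Dense 1-D linear-interpolation matrix, half-pixel-centre convention."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        s = (i + 0.5) * scale - 0.5
        lo = int(np.floor(s))
        f = s - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - f
        m[i, hi_c] += f
    return m


def upsample2x(x):
    """Bilinear 2x spatial upsampling (half-pixel centres)."""
    x = astensor(x)
    n, c, h, w = x.shape
    mh = _interp_matrix(2 * h, h, dtype=x.data.dtype)
    mw = _interp_matrix(2 * w, w, dtype=x.data.dtype)
    out = np.einsum("ih,nchw,jw->ncij", mh, x.data, mw, optimize=True)

    def bw(g, x=x, mh=mh, mw=mw):
        x._accum(np.einsum("ih,ncij,jw->nchw", mh, g, mw, optimize=True))
    return Tensor(out, parents=(x,), backward=bw)


def where_const(mask, a, b):
    """Select ``a`` where ``mask`` else ``b``; ``mask`` is a constant.

    Forward uses np.where, so unselected entries of the output are
    bit-identical to the corresponding input — no arithmetic touches them.
    """
    a, b = astensor(a), astensor(b)
    m = np.asarray(mask).astype(bool)
    out = np.where(m, a.data, b.data)

    def bw(g, a=a, b=b, m=m):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(m, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(m, 0.0, g), b.shape))
    return Tensor(out, parents=(a, b), backward=bw)


def channel_max(x):
    """Max over the channel axis, keepdims: (N, C, H, W) -> (N, 1, H, W)."""
    return astensor(x).max(axis=1, keepdims=True)
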