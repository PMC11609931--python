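"""Minimal reverse-mode automatic differentiation on numpy arrays.

Everything the model trains — convolutions, LSTM gates, attention, the
fusion head — is expressed through the handful of primitives below, so one
backward pass through the taped graph yields exact analytic gradients for
AdamW.  All arithmetic is float64; gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "div", "neg", "matmul",
    "exp", "log", "tanh", "sigmoid", "relu", "power", "tsum", "tmean",
    "reshape", "transpose", "concat", "stack", "getitem", "softmax",
    "conv2d", "maxpool2",
]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self):
        """Backpropagate from a scalar output through the taped graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data, parents, backward):
    return Tensor(data, parents=parents, backward=backward)


def _acc(t: Tensor, g) -> None:
    """Lazily accumulate a gradient contribution into ``t.grad``.

    The first contribution is copied (``g`` may alias a child's gradient
    or be a read-only broadcast view); later ones are added in place.
    """
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad += g


# -- elementwise arithmetic ------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            _acc(a, _unbroadcast(g, a.data.shape))
        if b.requires_grad:
            _acc(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            _acc(a, _unbroadcast(g, a.data.shape))
        if b.requires_grad:
            _acc(b, -(_unbroadcast(g, b.data.shape)))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            _acc(a, _unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            _acc(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            _acc(a, _unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            _acc(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            _acc(a, -(g))

    return _make(-a.data, (a,), backward)


def power(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            _acc(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


# -- nonlinearities --------------------------------------------------

def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            _acc(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            _acc(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            _acc(a, g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    """Logistic function, computed on the stable branch for either sign."""
    a = as_tensor(a)
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    out_data[~pos] = ez / (1.0 + ez)

    def backward(g):
        if a.requires_grad:
            _acc(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            _acc(a, g * (a.data > 0))

    return _make(out_data, (a,), backward)


# -- reductions and shape ops ----------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            _acc(a, np.broadcast_to(g, a.data.shape))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            _acc(a, np.broadcast_to(gg, a.data.shape))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis] if isinstance(axis, int) else int(
            np.prod([a.data.shape[ax] for ax in axis])
        )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = as_tensor(a)
    orig = a.data.shape

    def backward(g):
        if a.requires_grad:
            _acc(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes):
    a = as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            _acc(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(parts, axis=0):
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _acc(p, g[tuple(sl)])

    return _make(
        np.concatenate([p.data for p in parts], axis=axis), tuple(parts), backward
    )


def stack(parts, axis=0):
    parts = [as_tensor(p) for p in parts]

    def backward(g):
        slices = np.moveaxis(g, axis, 0)
        for p, gp in zip(parts, slices):
            if p.requires_grad:
                _acc(p, gp)

    return _make(np.stack([p.data for p in parts], axis=axis), tuple(parts), backward)


def getitem(a, idx):
    """Basic or advanced indexing; scatter-add on the way back."""
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            np.add.at(a.grad, idx, g)

    return _make(a.data[idx], (a,), backward)


# -- composite -------------------------------------------------------

def matmul(a, b):
    """Matrix product with numpy batch broadcasting; operands must be >= 2-D."""
    a, b = as_tensor(a), as_tensor(b)
    if a.data.ndim < 2 or b.data.ndim < 2:
        raise ValueError("matmul operands must be at least 2-D")
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            _acc(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            _acc(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def softmax(a, axis=-1):
    """Row-wise softmax with max-subtraction for numerical stability."""
    a = as_tensor(a)
    shift = np.max(a.data, axis=axis, keepdims=True)  # constant: detached
    e = exp(sub(a, shift))
    return div(e, tsum(e, axis=axis, keepdims=True))


def conv2d(x, w, b=None):
    """Valid cross-correlation, stride 1.

    x: [B, C, H, W]; w: [O, C, M, N]; b: [O] or None.  Implemented as
    im2col + matmul; the backward pass scatters gradients back through the
    column view (col2im as a loop over the M*N kernel offsets).
    """
    x, w = as_tensor(x), as_tensor(w)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
    B, C, H, W = x.data.shape
    O, Cw, M, N = w.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: image has {C}, kernel expects {Cw}")
    if M > H or N > W:
        raise ValueError(
            f"kernel {M}x{N} larger than image {H}x{W}"
        )
    Ho, Wo = H - M + 1, W - N + 1
    # [B, C, Ho, Wo, M, N] windows over the input
    win = np.lib.stride_tricks.sliding_window_view(x.data, (M, N), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * M * N)
    wmat = w.data.reshape(O, C * M * N)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            _acc(w, (gmat.T @ cols).reshape(O, C, M, N))
        if b is not None and b.requires_grad:
            _acc(b, gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, Ho, Wo, C, M, N)
            gx = np.zeros_like(x.data)
            for i in range(M):
                for j in range(N):
                    gx[:, :, i:i + Ho, j:j + Wo] += gcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            _acc(x, gx)

    return _make(out_data, tuple(parents), backward)


def maxpool2(x):
    """Non-overlapping 2x2 max pooling, stride 2; odd trailing row/col dropped.

    The window max is computed as a cascade of pairwise maxima over strided
    slices; the backward pass routes the gradient to one winner per window
    (earlier slice wins ties).
    """
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H < 2 or W < 2:
        raise ValueError(f"spatial dims ({H}x{W}) below the 2x2 pooling window")
    H2, W2 = H // 2, W // 2
    v = x.data[:, :, : 2 * H2, : 2 * W2]
    a = v[:, :, 0::2, 0::2]
    b = v[:, :, 0::2, 1::2]
    c = v[:, :, 1::2, 0::2]
    d = v[:, :, 1::2, 1::2]
    top_ab = a >= b
    m1 = np.where(top_ab, a, b)
    top_cd = c >= d
    m2 = np.where(top_cd, c, d)
    top = m1 >= m2
    out_data = np.where(top, m1, m2)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        g1 = g * top
        g2 = g - g1
        gx[:, :, 0::2, 0::2][:, :, :H2, :W2] = g1 * top_ab
        gx[:, :, 0::2, 1::2][:, :, :H2, :W2] = g1 * ~top_ab
        gx[:, :, 1::2, 0::2][:, :, :H2, :W2] = g2 * top_cd
        gx[:, :, 1::2, 1::2][:, :, :H2, :W2] = g2 * ~top_cd
        _acc(x, gx)

    return _make(out_data, (x,), backward)
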