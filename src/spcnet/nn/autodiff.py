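"""Reverse-mode autodiff core: Tensor plus the op set used by the network."""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "relu", "sigmoid", "log", "abs_", "clip",
    "sum_", "mean", "concat", "conv2d", "maxpool2x2", "upsample_bilinear",
    "resize_bilinear",
]


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this tensor w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for big images
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # operator sugar
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce `grad` back to `shape` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out, _parents=(a, b), _backward=backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)

    return Tensor(out, _parents=(a, b), _backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.data.shape), _unbroadcast(g * a.data, b.data.shape)

    return Tensor(out, _parents=(a, b), _backward=backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    # recompute the mask from the output in backward: retains no extra memory
    return Tensor(out, _parents=(x,), _backward=lambda g: (g * (out > 0),))


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(out, _parents=(x,), _backward=lambda g: (g * out * (1.0 - out),))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), _parents=(x,), _backward=lambda g: (g / x.data,))


def abs_(x: Tensor) -> Tensor:
    return Tensor(np.abs(x.data), _parents=(x,), _backward=lambda g: (g * np.sign(x.data),))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    def backward(g):
        return (g * ((x.data > lo) & (x.data < hi)),)

    return Tensor(np.clip(x.data, lo, hi), _parents=(x,), _backward=backward)


def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, x.data.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, x.data.shape).copy(),)

    return Tensor(out, _parents=(x,), _backward=backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    out = x.data.mean()
    return Tensor(out, _parents=(x,), _backward=lambda g: (np.broadcast_to(g / n, x.data.shape).copy(),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(data, _parents=tuple(tensors), _backward=backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, dilation: int = 1) -> Tensor:
    """'Same' zero-padded 2-D convolution, NCHW layout, stride 1.

    Implemented as a sum over kernel offsets of channel-mixing matmuls, which
    keeps memory bounded (no im2col buffer) and uses BLAS for the heavy part.
    """
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    ph, pw = dilation * (kh // 2), dilation * (kw // 2)

    def padded_input() -> np.ndarray:
        if ph or pw:
            return np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        return x.data

    # Memory discipline: backward recomputes the padded input and the
    # per-offset matrices from x.data instead of retaining them — keeping the
    # live graph small matters more than the extra copies on this class of
    # sandboxed hosts, where fresh large allocations page-fault expensively.
    xp = padded_input()
    xm = np.empty((c, n * h * w), dtype=x.data.dtype)
    out_mat = np.zeros((o, n * h * w), dtype=x.data.dtype)
    tmp = np.empty_like(out_mat)
    for a in range(kh):
        for b in range(kw):
            xs = xp[:, :, a * dilation : a * dilation + h, b * dilation : b * dilation + w]
            np.copyto(xm, xs.transpose(1, 0, 2, 3).reshape(c, -1))
            np.matmul(weight.data[:, :, a, b], xm, out=tmp)
            out_mat += tmp
    out = np.ascontiguousarray(out_mat.reshape(o, n, h, w).transpose(1, 0, 2, 3))
    del xp, xm, tmp, out_mat
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        xp = padded_input()
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, -1)
        xm = np.empty((c, n * h * w), dtype=x.data.dtype)
        dw = np.empty_like(weight.data)
        dxp = np.zeros_like(xp)
        dxm = np.empty((c, n * h * w), dtype=g.dtype)
        for a in range(kh):
            for b in range(kw):
                xs = xp[:, :, a * dilation : a * dilation + h, b * dilation : b * dilation + w]
                np.copyto(xm, xs.transpose(1, 0, 2, 3).reshape(c, -1))
                dw[:, :, a, b] = gm @ xm.T
                np.matmul(weight.data[:, :, a, b].T, gm, out=dxm)
                dxp[:, :, a * dilation : a * dilation + h, b * dilation : b * dilation + w] += (
                    dxm.reshape(c, n, h, w).transpose(1, 0, 2, 3)
                )
        dx = dxp[:, :, ph : ph + h, pw : pw + w] if (ph or pw) else dxp
        if bias is not None:
            return dx, dw, g.sum(axis=(0, 2, 3))
        return dx, dw

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    hh, ww = h // 2, w // 2
    xr = x.data.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh, ww, 4)
    arg = xr.argmax(axis=-1).astype(np.int8)  # values 0..3; keep the closure small
    out = np.take_along_axis(xr, arg[..., None].astype(np.intp), axis=-1)[..., 0]
    out = np.ascontiguousarray(out)

    def backward(g):
        gx = np.zeros((n, c, hh, ww, 4), dtype=g.dtype)
        np.put_along_axis(gx, arg[..., None].astype(np.intp), g[..., None], axis=-1)
        return (gx.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w),)

    return Tensor(out, _parents=(x,), _backward=backward)


@lru_cache(maxsize=64)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic linear-interpolation matrix mapping n_in -> n_out samples."""
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0.0, n_in - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = pos - i0
    m = np.zeros((n_out, n_in))
    np.add.at(m, (np.arange(n_out), i0), 1.0 - w1)
    np.add.at(m, (np.arange(n_out), i1), w1)
    m.setflags(write=False)
    return m


def _apply_interp(data: np.ndarray, mh: np.ndarray, mw: np.ndarray) -> np.ndarray:
    t = np.einsum("oh,nchw->ncow", mh, data, optimize=True)
    return np.einsum("pw,ncow->ncop", mw, t, optimize=True)


def upsample_bilinear(x: Tensor, scale: int = 2) -> Tensor:
    """Bilinear upsampling by an integer factor (half-pixel-centered sampling)."""
    n, c, h, w = x.data.shape
    mh = _interp_matrix(h, h * scale).astype(x.data.dtype)
    mw = _interp_matrix(w, w * scale).astype(x.data.dtype)
    out = _apply_interp(x.data, mh, mw)

    def backward(g):
        return (_apply_interp(g, mh.T, mw.T),)

    return Tensor(out, _parents=(x,), _backward=backward)


def resize_bilinear(data: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Plain-array bilinear resize (no autodiff); used for image pyramids."""
    if data.ndim == 2:
        return resize_bilinear(data[None, None], shape)[0, 0]
    mh = _interp_matrix(data.shape[2], shape[0]).astype(data.dtype)
    mw = _interp_matrix(data.shape[3], shape[1]).astype(data.dtype)
    return _apply_interp(data, mh, mw)
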