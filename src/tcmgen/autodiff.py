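"""Compact reverse-mode automatic differentiation on NumPy arrays.

The whole generator (recurrent encoder, attention decoder, multi-task loss)
is differentiated through this engine.  Design constraints:

* small dense tensors (hidden sizes of tens, vocabularies of hundreds), so
  per-op Python overhead dominates — ops stay minimal and allocation-light;
* float64 throughout, so finite-difference gradient checks are meaningful;
* a static tape: every ``Tensor`` records its parents and a backward
  closure, and :meth:`Tensor.backward` walks the tape in reverse
  topological order.

Only the primitives the model needs are provided (affine maps, pointwise
nonlinearities, softmax, concatenation, reductions).  Broadcasting follows
NumPy; gradients of broadcast operands are summed back to their shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "neg",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "softmax",
    "tsum",
    "mean",
    "concat",
    "stack",
    "dot",
    "scale",
    "getitem",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that NumPy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    extra = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if extra:
        grad = grad.sum(axis=extra, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: a value plus backward plumbing."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._prev = prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return neg(self)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad=False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, prev=(a, b))
    if out.requires_grad:
        def _bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))
        out._backward = _bw
    return out


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data - b.data, prev=(a, b))
    if out.requires_grad:
        def _bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g, b.data.shape))
        out._backward = _bw
    return out


def neg(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(-a.data, prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(-g)
        out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, prev=(a, b))
    if out.requires_grad:
        def _bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))
        out._backward = _bw
    return out


def scale(a, c: float) -> Tensor:
    """Multiply by a Python constant (cheaper than mul with a wrapped scalar)."""
    a = _wrap(a)
    out = Tensor(a.data * c, prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(g * c)
        out._backward = _bw
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, prev=(a, b))
    if out.requires_grad:
        ad, bd = a.data, b.data
        def _bw(g):
            if a.requires_grad:
                if ad.ndim == 1 and bd.ndim == 2:
                    a._accumulate(g @ bd.T)
                elif ad.ndim == 2 and bd.ndim == 1:
                    a._accumulate(np.outer(g, bd))
                elif ad.ndim == 1 and bd.ndim == 1:
                    a._accumulate(g * bd)
                else:
                    a._accumulate(g @ bd.swapaxes(-1, -2))
            if b.requires_grad:
                if ad.ndim == 1 and bd.ndim == 2:
                    b._accumulate(np.outer(ad, g))
                elif ad.ndim == 2 and bd.ndim == 1:
                    b._accumulate(ad.T @ g)
                elif ad.ndim == 1 and bd.ndim == 1:
                    b._accumulate(g * ad)
                else:
                    b._accumulate(ad.swapaxes(-1, -2) @ g)
        out._backward = _bw
    return out


def dot(a, b) -> Tensor:
    """Inner product of two vectors."""
    return matmul(a, b)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(y, prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(g * y * (1.0 - y))
        out._backward = _bw
    return out


def tanh(a) -> Tensor:
    a = _wrap(a)
    y = np.tanh(a.data)
    out = Tensor(y, prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(g * (1.0 - y * y))
        out._backward = _bw
    return out


def relu(a) -> Tensor:
    a = _wrap(a)
    y = np.maximum(a.data, 0.0)
    out = Tensor(y, prev=(a,))
    if out.requires_grad:
        mask = (a.data > 0.0).astype(np.float64)
        def _bw(g):
            a._accumulate(g * mask)
        out._backward = _bw
    return out


def exp(a) -> Tensor:
    a = _wrap(a)
    y = np.exp(a.data)
    out = Tensor(y, prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(g * y)
        out._backward = _bw
    return out


def log(a, eps: float = 0.0) -> Tensor:
    """Natural log; ``eps`` clamps the argument away from zero if given."""
    a = _wrap(a)
    x = a.data if eps == 0.0 else np.maximum(a.data, eps)
    out = Tensor(np.log(x), prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(g / x)
        out._backward = _bw
    return out


def softmax(a) -> Tensor:
    """Softmax over the last axis."""
    a = _wrap(a)
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, prev=(a,))
    if out.requires_grad:
        def _bw(g):
            a._accumulate(y * (g - (g * y).sum(axis=-1, keepdims=True)))
        out._backward = _bw
    return out


def tsum(a, axis=None) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis), prev=(a,))
    if out.requires_grad:
        shape = a.data.shape
        def _bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, shape))
            else:
                a._accumulate(np.broadcast_to(np.expand_dims(g, axis), shape))
        out._backward = _bw
    return out


def mean(a, axis=None) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(tsum(a, axis=axis), 1.0 / n)


def concat(parts, axis: int = 0) -> Tensor:
    parts = [_wrap(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), prev=tuple(parts))
    if out.requires_grad:
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)
        def _bw(g):
            for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
                if p.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    p._accumulate(g[tuple(idx)])
        out._backward = _bw
    return out


def stack(parts, axis: int = 0) -> Tensor:
    parts = [_wrap(p) for p in parts]
    out = Tensor(np.stack([p.data for p in parts], axis=axis), prev=tuple(parts))
    if out.requires_grad:
        def _bw(g):
            for i, p in enumerate(parts):
                if p.requires_grad:
                    p._accumulate(np.take(g, i, axis=axis))
        out._backward = _bw
    return out


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data[idx], prev=(a,))
    if out.requires_grad:
        shape = a.data.shape
        def _bw(g):
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, idx, g)
            a._accumulate(full)
        out._backward = _bw
    return out
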