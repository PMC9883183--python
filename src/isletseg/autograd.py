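"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``
and records, for each produced tensor, the parent tensors and a closure
that propagates the output gradient back to them.  ``Tensor.backward``
replays the tape in reverse topological order.  Only the operations the
segmentation network needs are implemented; every primitive has a
hand-written backward pass, which keeps training on a single CPU fast
enough to be practical.

All array data is kept in whatever dtype the caller supplies (the network
uses float32); gradients are accumulated in the same dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax_rows"]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = _make((self, other), self.data + other.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = _make((self, other), self.data * other.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Matrix product; supports 2-D and batched 3-D operands."""
        out = _make((self, other), np.matmul(self.data, other.data))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        out = _make((self,), self.data.transpose(*axes))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        out._backward = bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = _make((self,), self.data.reshape(*shape))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def sum(self) -> "Tensor":
        out = _make((self,), np.asarray(self.data.sum(), dtype=self.data.dtype))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))

        out._backward = bwd
        return out

    # -- nonlinearities ---------------------------------------------------

    def relu(self) -> "Tensor":
        out = _make((self,), np.maximum(self.data, 0))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        y = np.empty_like(self.data)
        pos = self.data >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        y[~pos] = e / (1.0 + e)
        out = _make((self,), y)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = _make((self,), np.log(self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only where unclipped."""
        out = _make((self,), np.clip(self.data, lo, hi))
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _make(parents: tuple, data: np.ndarray) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = parents
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors: list, axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = _make(tuple(tensors), data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Softmax along the last axis, max-shifted for overflow safety."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    a = e / e.sum(axis=-1, keepdims=True)
    out = _make((x,), a)

    def bwd(g):
        if x.requires_grad:
            dot = (g * a).sum(axis=-1, keepdims=True)
            x._accum(a * (g - dot))

    out._backward = bwd
    return out
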