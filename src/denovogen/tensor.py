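"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the generator networks need: affine maps,
pointwise nonlinearities, softmax cross-entropy, embedding lookups, reductions
and concatenation. Gradients are accumulated into ``Tensor.grad`` by calling
``backward()`` on a scalar result. Float64 throughout so training runs are
bit-reproducible on a single machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- graph construction helpers --------------------------------------

    @staticmethod
    def _unbroadcast(g, shape):
        """Sum-reduce gradient g back to a broadcast operand's shape."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, n in enumerate(shape):
            if n == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rmul__(self, other):
        return self * other

    def __radd__(self, other):
        return self + other

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.data.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        return self.matmul(other)

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(y, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g / n))

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose_last2(self):
        out = Tensor(np.swapaxes(self.data, -1, -2), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, -1, -2))

        out._backward = bwd
        return out

    def take_rows(self, idx) -> "Tensor":
        """Embedding-style lookup: rows of a 2-D parameter by integer index."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, idx.reshape(-1),
                          g.reshape(-1, self.data.shape[1]))

        out._backward = bwd
        return out

    def masked_fill(self, mask, value: float) -> "Tensor":
        """Set entries where mask is True to a constant (no gradient there)."""
        y = np.where(mask, value, self.data)
        out = Tensor(y, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.where(mask, 0.0, g))

        out._backward = bwd
        return out

    def log_softmax(self, axis=-1) -> "Tensor":
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse
        out = Tensor(y, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                sm = np.exp(y)
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        out._backward = bwd
        return out

    def softmax(self, axis=-1) -> "Tensor":
        ls = self.log_softmax(axis=axis)
        y = np.exp(ls.data)
        out = Tensor(y, _prev=(ls,))

        def bwd(g):
            if ls.requires_grad:
                ls._accum(g * y)

        out._backward = bwd
        return out

    # -- autodiff driver ---------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(())[()] if self.data.ndim == 0
                     else self.data.reshape(-1)[0])

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis=0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def bwd(g):
        start = 0
        for t, n in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + n)
            if t.requires_grad:
                t._accum(g[tuple(sl)])
            start += n

    out._backward = bwd
    return out


def stack(tensors, axis=0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    out._backward = bwd
    return out
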