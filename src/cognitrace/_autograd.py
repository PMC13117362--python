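"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the model stack needs: affine maps, pointwise
nonlinearities, softmax/log-softmax, row gathering (embedding lookup), row
concatenation and reductions. Gradients are accumulated in float64 and the
whole graph is torn down after :func:`backward`, so memory stays bounded at
desk scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "param", "const"]


class Tensor:
    """A node in the computation graph.

    Parameters hold gradients (``requires_grad=True``); constants do not.
    All arithmetic promotes plain ndarrays/scalars to constant tensors.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        g = np.asarray(g, dtype=np.float64)
        # collapse broadcast dimensions back onto self.shape
        while g.ndim > self.data.ndim:
            g = g.sum(axis=0)
        for ax, n in enumerate(self.data.shape):
            if n == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t is not self and not t.requires_grad:
                t.grad = None if t._backward is not None else t.grad

    # -- constructors -------------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
            else:
                self._accum(g @ b.T)
                other._accum(a.T @ g)

        out._backward = bw
        return out

    def __pow__(self, p):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # -- nonlinearities -----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor(y, parents=(self,))

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._accum(g * dy)

        out._backward = bw
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    def take_rows(self, idx):
        """Gather rows (embedding lookup); gradient scatter-adds."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = bw
        return out

    def slice(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            acc[key] = g
            self._accum(acc)

        out._backward = bw
        return out

    def softmax(self):
        """Softmax over the last axis."""
        x = self.data
        m = x.max(axis=-1, keepdims=True)
        e = np.exp(x - m)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, parents=(self,))

        def bw(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            self._accum(y * (g - dot))

        out._backward = bw
        return out

    def log_softmax(self):
        x = self.data
        m = x.max(axis=-1, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        y = z - lse
        out = Tensor(y, parents=(self,))

        def bw(g):
            p = np.exp(y)
            self._accum(g - p * g.sum(axis=-1, keepdims=True))

        out._backward = bw
        return out


def concat_rows(tensors):
    """Concatenate 1-D tensors into one long vector (differentiable)."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.size for t in tensors]
    out = Tensor(np.concatenate([t.data.ravel() for t in tensors]), parents=tuple(tensors))

    def bw(g):
        off = 0
        for t, n in zip(tensors, sizes):
            t._accum(g[off:off + n].reshape(t.data.shape))
            off += n

    out._backward = bw
    return out


def stack_rows(tensors):
    """Stack 1-D tensors of equal length into a 2-D tensor (differentiable)."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors]), parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(g[i])

    out._backward = bw
    return out


def param(array):
    """Wrap an array as a trainable parameter."""
    return Tensor(np.asarray(array, dtype=np.float64), requires_grad=True)


def const(array):
    """Wrap an array as a non-trainable constant."""
    return Tensor(np.asarray(array, dtype=np.float64), requires_grad=False)
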