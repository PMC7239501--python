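"""A compact reverse-mode autodiff tensor on top of numpy.

Only the operations the adaptation networks need are implemented; every op
stores a closure computing the vector-Jacobian product. Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological
sweep. All data is float32; shapes follow numpy broadcasting, with gradients
summed back down to each parent's shape.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (forward passes only)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over broadcast dimensions so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                g = _unbroadcast(np.asarray(g, dtype=np.float32), p.data.shape)
                p.grad = g if p.grad is None else p.grad + g

    def zero_grad(self):
        self.grad = None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._result(self.data + other.data, (self, other),
                              lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._result(self.data * other.data, (self, other),
                              lambda g: (g * other.data, g * self.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._result(
            self.data / other.data, (self, other),
            lambda g: (g / other.data,
                       -g * self.data / (other.data * other.data)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        d = self.data
        return Tensor._result(d ** p, (self,),
                              lambda g: (g * p * d ** (p - 1),))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._result(a @ b, (self, other),
                              lambda g: (g @ b.T, a.T @ g))

    def __matmul__(self, other):
        return self.matmul(other)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._result(self.data.reshape(*shape), (self,),
                              lambda g: (g.reshape(old),))

    def sum(self):
        shape = self.data.shape
        return Tensor._result(self.data.sum(), (self,),
                              lambda g: (np.broadcast_to(g, shape),))

    def mean(self):
        n = self.data.size
        shape = self.data.shape
        return Tensor._result(self.data.mean(), (self,),
                              lambda g: (np.broadcast_to(g / n, shape),))

    # -- elementwise nonlinearities ------------------------------------------
    def log(self):
        d = self.data
        return Tensor._result(np.log(d), (self,), lambda g: (g / d,))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._result(out, (self,), lambda g: (g * out,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._result(out, (self,), lambda g: (g * (1.0 - out * out),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._result(out, (self,), lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.data > 0
        return Tensor._result(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        d = self.data
        neg = d < 0
        out = d.copy()
        out[neg] *= slope
        def backward(g):
            dg = g.copy()
            dg[neg] *= slope
            return (dg,)
        return Tensor._result(out, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the bounds."""
        d = self.data
        mask = (d >= lo) & (d <= hi)
        return Tensor._result(np.clip(d, lo, hi), (self,), lambda g: (g * mask,))

    def gather_rows(self, index: np.ndarray):
        """Select one column per row: out[i] = self[i, index[i]]."""
        index = np.asarray(index, dtype=np.intp)
        rows = np.arange(self.data.shape[0])
        out = self.data[rows, index]

        def backward(g):
            full = np.zeros_like(self.data)
            full[rows, index] = g
            return (full,)

        return Tensor._result(out, (self,), backward)

    def softmax(self):
        """Row-wise softmax of a 2-D logit matrix."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=1, keepdims=True)
            return (p * (g - dot),)

        return Tensor._result(p, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
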