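"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small tape: just the operations the recurrent
architecture needs (broadcasted arithmetic, matmul, tanh/sigmoid, sqrt,
axis reductions, concatenation). Gradients are accumulated into ``.grad``
by :meth:`Var.backward`, which walks the tape in reverse topological
order. Correctness is pinned by finite-difference tests rather than by
generality — do not add ops without a gradcheck.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "_parents", "_vjps", "requires_grad")

    def __init__(self, value, parents=(), vjps=(), requires_grad=True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._vjps = vjps
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Var":
        if isinstance(other, Var):
            return other
        return Var(other, requires_grad=False)

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        return Var(
            self.value + other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g, self.value.shape),
                lambda g: _unbroadcast(g, other.value.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Var(-self.value, parents=(self,), vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Var(
            self.value * other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g * other.value, self.value.shape),
                lambda g: _unbroadcast(g * self.value, other.value.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Var(
            self.value / other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g / other.value, self.value.shape),
                lambda g: _unbroadcast(
                    -g * self.value / other.value**2, other.value.shape
                ),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        return Var(
            self.value @ other.value,
            parents=(self, other),
            vjps=(
                lambda g: g @ other.value.T,
                lambda g: self.value.T @ g,
            ),
        )

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        out = np.tanh(self.value)
        return Var(out, parents=(self,), vjps=(lambda g: g * (1.0 - out**2),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.value))
        return Var(out, parents=(self,), vjps=(lambda g: g * out * (1.0 - out),))

    def sqrt(self):
        out = np.sqrt(self.value)
        return Var(out, parents=(self,), vjps=(lambda g: g * 0.5 / out,))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.value.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.value.shape).copy()

        return Var(out, parents=(self,), vjps=(vjp,))

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backward ----------------------------------------------------------

    def backward(self, seed=None):
        """Accumulate d(self)/d(leaf) into every reachable ``.grad``."""
        topo: list[Var] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = (
            np.ones_like(self.value)
            if seed is None
            else np.asarray(seed, dtype=np.float64)
        )
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib


def concat(vars_: list, axis: int = -1) -> Var:
    """Concatenate Vars along ``axis`` with gradient routing by slicing."""
    vars_ = [Var._lift(v) for v in vars_]
    values = [v.value for v in vars_]
    out = np.concatenate(values, axis=axis)
    sizes = [v.shape[axis] for v in values]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Var(
        out,
        parents=tuple(vars_),
        vjps=tuple(make_vjp(i) for i in range(len(vars_))),
    )
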