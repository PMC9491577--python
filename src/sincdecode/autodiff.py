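"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The decoding networks in this package (the sinc filter-bank classifier, the
squeeze-and-excitation attention gate, and the EEG-conditioned generator)
need gradients through custom parameterizations — band-pass kernels built
from two scalars per filter, multiplicative attention gates, and the
weighted-Gaussian conditioning layer.  This module provides the small tape
of array operations those networks are built from: a :class:`Tensor`
wrapping an ``ndarray`` with a gradient slot, elementwise and reduction
primitives with broadcasting, and ``backward`` running reverse topological
order over the recorded graph.

Gradient correctness is checked against central finite differences in the
test suite.  A module-level switch (:func:`no_grad`) disables graph
recording for evaluation-mode forward passes.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager: skip recording the backward graph (eval mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def make(data: np.ndarray, parents: Sequence["Tensor"],
             backward: Callable[[np.ndarray], None]) -> "Tensor":
        """Create a graph node; records parents only while grad is enabled."""
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data + b.data

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor.make(out_data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data * b.data

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor.make(out_data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        b = Tensor._wrap(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bwd(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor.make(out_data, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data @ b.data

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor.make(out_data, (a, b), bwd)

    # -- shape ----------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def bwd(g):
            a._accumulate(g.reshape(a.shape))

        return Tensor.make(out_data, (a,), bwd)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = a.data.transpose(axes)

        def bwd(g):
            a._accumulate(g.transpose(inv))

        return Tensor.make(out_data, (a,), bwd)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor.make(out_data, (a,), bwd)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy()
                              if np.ndim(g) else np.full(a.shape, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor.make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims=False):
        """Max over one axis; gradient flows to the (first) argmax."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)
        arg = a.data.argmax(axis=axis)

        def bwd(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(arg, axis), gg, axis)
            a._accumulate(full)

        return Tensor.make(out_data, (a,), bwd)

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor.make(out_data, (a,), bwd)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor.make(out_data, (a,), bwd)

    def sin(self):
        a = self
        out_data = np.sin(a.data)

        def bwd(g):
            a._accumulate(g * np.cos(a.data))

        return Tensor.make(out_data, (a,), bwd)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        a = self
        out_data = np.abs(a.data)
        sign = np.sign(a.data)

        def bwd(g):
            a._accumulate(g * sign)

        return Tensor.make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0
        out_data = a.data * mask

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor.make(out_data, (a,), bwd)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = a.data <= 0
        out_data = np.where(neg, alpha * np.expm1(a.data), a.data)

        def bwd(g):
            a._accumulate(g * np.where(neg, out_data + alpha, 1.0))

        return Tensor.make(out_data, (a,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        fac = np.where(a.data > 0, 1.0, slope)
        out_data = a.data * fac

        def bwd(g):
            a._accumulate(g * fac)

        return Tensor.make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor.make(out_data, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accumulate(g * (1.0 - out_data ** 2))

        return Tensor.make(out_data, (a,), bwd)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor.make(out_data, tensors, bwd)
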