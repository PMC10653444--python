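"""Reverse-mode automatic differentiation on dense numpy arrays.

A deliberately small tape-based engine: every operation builds a node
holding references to its parent :class:`Tensor` objects and a closure
that maps the output gradient to parent-gradient contributions.
``float32`` is used throughout so the convolution kernels hit BLAS
single-precision matrix products.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "add", "sub", "mul", "div", "tsum", "sigmoid", "prelu", "concat"]


class Tensor:
    """A dense array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).reshape(self.data.shape).copy()
        else:
            self.grad += np.asarray(g, dtype=np.float32).reshape(self.data.shape)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological order (graphs can be ~100s of nodes deep)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free tape state as soon as it has been consumed
                node._backward = None
                node._parents = ()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def sum(self):
        return tsum(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _tracked(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def make_node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _tracked(*parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return make_node(out, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data - b.data

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(-g, b.data.shape))

    return make_node(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return make_node(out, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data / b.data

    def backward(g):
        a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return make_node(out, (a, b), backward)


def tsum(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = np.asarray(a.data.sum(dtype=np.float64), dtype=np.float32)

    def backward(g):
        a.accumulate(np.broadcast_to(g, a.data.shape))

    return make_node(out, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    out[~pos] = e / (1.0 + e)
    # keep probabilities strictly inside (0, 1) under float32 saturation
    np.clip(out, 1e-6, 1.0 - 1e-6, out=out)

    def backward(g):
        a.accumulate(g * out * (1.0 - out))

    return make_node(out, (a,), backward)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU with one learnable slope per channel (last axis)."""
    x, slope = _as_tensor(x), _as_tensor(slope)
    a = slope.data  # (C,) broadcasts over the channels-last layout
    neg = np.minimum(x.data, 0.0)
    out = np.maximum(x.data, 0.0) + a * neg

    def backward(g):
        gx = np.where(x.data > 0, g, a * g)
        x.accumulate(gx)
        ga = (g * neg).reshape(-1, slope.data.size).sum(axis=0)
        slope.accumulate(ga)

    return make_node(out, (x, slope), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    return make_node(out, tuple(tensors), backward)
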