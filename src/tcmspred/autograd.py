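"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the fusion network: broadcast-aware arithmetic,
(batched) matmul, the sigmoid/tanh/relu nonlinearities, masked softmax,
concatenation, axis reductions, and embedding lookup with scatter-add
backward.  Graphs are built eagerly; ``Tensor.backward()`` runs a
topological sweep.  Everything is float64.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows", "embedding_lookup",
           "masked_softmax", "sigmoid", "tanh", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape))
        out._backward = back
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def back(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))
        out._backward = back
        return out

    __matmul__ = matmul

    # ---- reductions and reshaping ----------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = back
        return out

    def transpose_last(self) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, -1, -2), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, -1, -2))
        out._backward = back
        return out

    def slice(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)
        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = back
        return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))
    out._backward = back
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - y * y))
    out._backward = back
    return out


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    out = Tensor(y, parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))
    out._backward = back
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = back
    return out


def stack_rows(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Stack same-shaped tensors along a new axis."""
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def back(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))
    out._backward = back
    return out


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup with scatter-add backward; index -1 maps to a zero row."""
    safe = np.where(indices < 0, 0, indices)
    picked = table.data[safe]
    picked[indices < 0] = 0.0
    out = Tensor(picked, parents=(table,))

    def back(g):
        if table.requires_grad:
            full = np.zeros_like(table.data)
            g_eff = np.where((indices >= 0)[..., None], g, 0.0)
            np.add.at(full, safe, g_eff)
            table._accumulate(full)
    out._backward = back
    return out


def masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax over the last axis, exactly zero at masked keys.

    ``mask`` broadcasts against ``logits``; rows with no valid key raise.
    """
    m = np.broadcast_to(mask, logits.data.shape)
    if not m.any(axis=-1).all():
        raise ValueError("softmax row with no valid key positions")
    x = np.where(m, logits.data, -np.inf)
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    e = np.where(m, e, 0.0)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, parents=(logits,))

    def back(g):
        if logits.requires_grad:
            dot = (g * y).sum(axis=-1, keepdims=True)
            logits._accumulate(y * (g - dot))
    out._backward = back
    return out
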