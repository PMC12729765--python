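"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` (float64) and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients.  The op set is exactly what the
dual-branch contrastive model needs: broadcasting arithmetic, (batched)
matmul, the usual pointwise nonlinearities, reductions, indexing, reshaping
and concatenation.  Gradients are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (inference / metric code)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents: Iterable["Tensor"], backward):
        parents = tuple(parents)
        needs = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs and _GRAD_ENABLED)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- basic properties --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)
            return (ga, gb)

        return Tensor._make(out_data, (a, b), backward)

    # -- pointwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            return (g / self.data,)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data**2),)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.data.shape

        def backward(g):
            return (g.reshape(src_shape),)

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            return (np.swapaxes(g, a, b),)

        return Tensor._make(out_data, (self,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src_shape = self.data.shape

        def backward(g):
            full = np.zeros(src_shape)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node.requires_grad and node._backward is None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


# -- free functions ----------------------------------------------------------
def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    req = [t for t in tensors if t.requires_grad]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(p for t, p in zip(tensors, pieces) if t.requires_grad)

    return Tensor._make(out_data, req, backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    req = [t for t in tensors if t.requires_grad]

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple(
            np.squeeze(p, axis=axis) for t, p in zip(tensors, pieces) if t.requires_grad
        )

    return Tensor._make(out_data, req, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max-shift is treated as a constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps).sqrt()
    return x / norm
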