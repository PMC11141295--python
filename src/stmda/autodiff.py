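"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model is trained full-batch on CPU with float64 arithmetic, so a compact
tape-based engine suffices: every op records its parents and a closure that
accumulates gradients; :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the ops the network and losses need are provided.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat_rows", "gather_pairs", "softmax_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over dimensions that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape.

    Parameters
    ----------
    data:
        Array (or scalar) value; stored as float64.
    requires_grad:
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(parents)
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # Stored arrays are never mutated in place (accumulation reallocates),
        # so incoming gradients can be kept by reference even when an op
        # passes the same array to several parents.
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accum(g)
            other._accum(-g)

        return Tensor._make(self.data - other.data, (self, other), backward)

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def backward(g):
            self._accum(g * np.where(pos, 1.0, out_data + alpha))

        return Tensor._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        pos = self.data > 0

        def backward(g):
            self._accum(g * pos)

        return Tensor._make(np.where(pos, self.data, 0.0), (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g_exp, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            count = np.prod([self.data.shape[a]
                             for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # --------------------------------------------------------------- shaping
    @property
    def T(self) -> "Tensor":
        def backward(g):
            self._accum(g.T)

        return Tensor._make(self.data.T, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def take_columns(self, idx: np.ndarray) -> "Tensor":
        """Select columns ``idx`` (any integer array shape) of a 2-D tensor."""
        idx = np.asarray(idx)
        flat_idx = idx.ravel()

        def backward(g):
            grad = np.zeros_like(self.data)
            g2 = g.reshape(self.data.shape[0], -1)
            # scatter-add duplicated column selections back
            np.add.at(grad.T, flat_idx, g2.T)
            self._accum(grad)

        return Tensor._make(self.data[:, idx], (self,), backward)


def concat_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            t._accum(g[a:b])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=0),
                        tensors, backward)


def gather_pairs(gram: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``out[i, a, b] = gram[idx[i, a], idx[i, b]]``.

    ``gram`` is an N x N (kernel) matrix and ``idx`` an integer array of
    neighbor lists, shape (N, k).  Used to evaluate per-spot local kernel
    sums for the spatially local alignment loss.
    """
    idx = np.asarray(idx)
    rows = idx[:, :, None]
    cols = idx[:, None, :]

    def backward(g):
        grad = np.zeros_like(gram.data)
        r = np.broadcast_to(rows, g.shape)
        c = np.broadcast_to(cols, g.shape)
        np.add.at(grad, (r.ravel(), c.ravel()), g.ravel())
        gram._accum(grad)

    return Tensor._make(gram.data[rows, cols], (gram,), backward)


def softmax_rows(logits: Tensor) -> Tensor:
    """Softmax along axis 0 of a 2-D tensor (columns are independent).

    The stabilizing shift uses the detached column max — softmax is invariant
    to it, so it carries no gradient.
    """
    shift = np.max(logits.data, axis=0, keepdims=True)
    e = (logits - shift).exp()
    return e / e.sum(axis=0, keepdims=True)
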