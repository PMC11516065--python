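"""Compact reverse-mode automatic differentiation on NumPy arrays.

The model in :mod:`drugformer.model` is small (tens of thousands of
parameters at the configurations this package targets), so a thin tape-based
autodiff layer over NumPy is sufficient to train it with Adam on a single
CPU.  Only the operations the model needs are implemented; every backward
rule is checked against central finite differences in the test suite.

Broadcasting follows NumPy semantics: gradients flowing into a broadcast
operand are summed back down to that operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = backward
        self._parents = parents
        self.name = name

    # -- bookkeeping ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}{tag}, grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many encoder layers)
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data
        a, b = self, other

        def bw(g):
            if a.requires_grad or a._backward:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad or b._backward:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor(-a.data, parents=(a,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(a.data * b.data, parents=(a, b), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self, other
        out_data = a.data @ b.data

        def bw(g):
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=bw)

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accumulate(g.reshape(orig))

        return Tensor(a.data.reshape(shape), parents=(a,), backward=bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))

        def bw(g):
            a._accumulate(g.transpose(inv))

        return Tensor(a.data.transpose(axes), parents=(a,), backward=bw)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows along the first axis (embedding / alignment lookup)."""
        idx = np.asarray(indices)
        a = self

        def bw(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, idx.reshape(-1), g.reshape(-1, *a.data.shape[1:]))
            a._accumulate(grad)

        return Tensor(a.data[idx], parents=(a,), backward=bw)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor(out_data, parents=(a,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities --------------------------------------------------

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * mask)

        return Tensor(np.where(mask, a.data, 0.0), parents=(a,), backward=bw)

    def leaky_relu(self, slope: float) -> "Tensor":
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor(np.where(mask, a.data, slope * a.data), parents=(a,), backward=bw)

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(a,), backward=bw)

    def log(self) -> "Tensor":
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor(np.log(a.data), parents=(a,), backward=bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bw(g):
            a._accumulate(g * mask)

        return Tensor(np.clip(a.data, lo, hi), parents=(a,), backward=bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

        return Tensor(out_data, parents=(a,), backward=bw)

    def layernorm(self, eps: float = 1e-5) -> "Tensor":
        """Normalize the last axis to zero mean / unit variance (no affine)."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        var = a.data.var(axis=-1, keepdims=True)
        ivar = 1.0 / np.sqrt(var + eps)
        xhat = (a.data - mu) * ivar

        def bw(g):
            gm = g.mean(axis=-1, keepdims=True)
            gx = (g * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(ivar * (g - gm - xhat * gx))

        return Tensor(xhat, parents=(a,), backward=bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * p.grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
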