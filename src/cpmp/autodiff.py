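"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to train the bag-level transformer: a :class:`Tensor`
wrapping an ndarray, a handful of primitive ops with hand-derived vector-
Jacobian products, and topological-order backpropagation.  Ops cover exactly
what the model needs (matmul, broadcast add/mul, ReLU, sigmoid, row softmax,
fused layer-norm, concatenation, slicing, reductions).

Gradient correctness is guarded by finite-difference checks in the test
suite rather than by construction, so keep new ops honest: every op must
un-broadcast its gradient back to the parent's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat_rows", "layer_norm", "softmax_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- primitives ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accumulate(full)

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = bwd
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g)))

        out._backward = bwd
        return out

    def mean(self):
        return self.sum() / self.data.size

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def square(self):
        return self * self


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax (last axis) with max-subtraction for stability."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(y * (g - (g * y).sum(axis=-1, keepdims=True)))

    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    d = x.data.shape[-1]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(
                _unbroadcast((g * xhat).sum(axis=tuple(range(g.ndim - 1))), gamma.shape)
            )
        if beta.requires_grad:
            beta._accumulate(
                _unbroadcast(g.sum(axis=tuple(range(g.ndim - 1))), beta.shape)
            )
        if x.requires_grad:
            gy = g * gamma.data
            x._accumulate(
                inv
                * (
                    gy
                    - gy.mean(axis=-1, keepdims=True)
                    - xhat * (gy * xhat).mean(axis=-1, keepdims=True)
                )
            )

    out._backward = bwd
    return out


def concat_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0),
                 parents=tuple(tensors))
    offsets = np.cumsum([0] + [t.data.shape[0] for t in tensors])

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(g[a:b])

    out._backward = bwd
    return out
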