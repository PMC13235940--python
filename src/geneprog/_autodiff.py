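"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training objective couples a graph-convolutional encoder, a row-softmax
pooling step and an MLP head through cut/orthogonality penalties, so its
gradient is tedious to derive and maintain by hand.  This module provides a
small tape-based tensor type with exactly the operations that objective
needs (dense/sparse matmul, broadcasted arithmetic, ReLU, row softmax,
stable cross-entropy primitives) plus an Adam optimizer.  Everything is
float64; correctness is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        value,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.grad: np.ndarray | None = None

    # -- graph traversal ---------------------------------------------------
    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node.parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.requires_grad and self.grad is not None:
            self.grad += _unbroadcast(np.asarray(grad, dtype=np.float64), self.value.shape)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def constant(value) -> "Tensor":
        return Tensor(value)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._wrap(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.value + other.value, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.value, (self,), lambda g: self._accum(-g))

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)

        def bwd(g):
            self._accum(g * other.value)
            other._accum(g * self.value)

        return Tensor(self.value * other.value, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._wrap(other)

        def bwd(g):
            self._accum(g / other.value)
            other._accum(-g * self.value / other.value**2)

        return Tensor(self.value / other.value, (self, other), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)

        def bwd(g):
            self._accum(g @ other.value.T)
            other._accum(self.value.T @ g)

        return Tensor(self.value @ other.value, (self, other), bwd)

    @property
    def T(self) -> "Tensor":
        return Tensor(self.value.T, (self,), lambda g: self._accum(g.T))

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self) -> "Tensor":
        mask = self.value > 0
        return Tensor(self.value * mask, (self,), lambda g: self._accum(g * mask))

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.value)
        return Tensor(out, (self,), lambda g: self._accum(g * 0.5 / out))

    def sum(self) -> "Tensor":
        return Tensor(self.value.sum(), (self,), lambda g: self._accum(np.broadcast_to(g, self.value.shape)))

    def mean(self) -> "Tensor":
        n = self.value.size
        return Tensor(
            self.value.mean(),
            (self,),
            lambda g: self._accum(np.broadcast_to(g / n, self.value.shape)),
        )

    def row_softmax(self) -> "Tensor":
        z = self.value - self.value.max(axis=1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=1, keepdims=True)

        def bwd(g):
            self._accum(s * (g - (g * s).sum(axis=1, keepdims=True)))

        return Tensor(s, (self,), bwd)


def spmm(M, x: Tensor) -> Tensor:
    """Product ``M @ x`` with a constant (possibly sparse) left operand."""
    MT = M.T

    def bwd(g):
        x._accum(MT @ g)

    return Tensor(np.asarray(M @ x.value), (x,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero entries with prob ``p``, rescale by 1/(1-p)."""
    if p <= 0:
        return x
    mask = (rng.random(x.value.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE, numerically stable: mean(softplus(z) - y*z)."""
    z = logits.value
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    val = np.mean(np.logaddexp(0.0, z) - y * z)
    n = z.size

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        logits._accum(g * (p - y) / n)

    return Tensor(val, (logits,), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multinomial cross-entropy against integer class labels."""
    z = logits.value
    labels = np.asarray(labels, dtype=np.intp)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    n = z.shape[0]
    val = np.mean(lse - z[np.arange(n), labels])

    def bwd(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)

    return Tensor(val, (logits,), bwd)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, value):
        super().__init__(value, requires_grad=True)


class Adam:
    """Adam with L2 regularization folded into the gradient.

    The weight-decay term is added to the raw gradient before the moment
    updates (the classic coupled formulation), so ``weight_decay`` matches
    the behaviour most deep-learning frameworks give for their plain Adam.
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_values(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]
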