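"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the attention-MIL and autoencoder
losses need: affine maps, element-wise nonlinearities, broadcasting
arithmetic, reductions, and a numerically stable softmax /
binary-cross-entropy-with-logits.  Gradients are accumulated by a
topological backward sweep, with broadcast axes summed out so that
parameter gradients always match the parameter shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "softmax", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, value, parents, backward) -> "Tensor":
        out = Tensor(value)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.value)
        # topological order via iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.value.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        value = self.value + other.value

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.value, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        value = self.value * other.value

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.value)
            if other.requires_grad:
                other._accum(g * self.value)

        return self._make(value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        value = self.value / other.value

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.value)
            if other.requires_grad:
                other._accum(-g * self.value / other.value**2)

        return self._make(value, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        value = self.value @ other.value

        def backward(g):
            a, b = self.value, other.value
            if self.requires_grad:
                if b.ndim == 1:
                    self._accum(np.outer(g, b) if a.ndim == 2 else g * b)
                else:
                    self._accum(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1:
                    other._accum(np.outer(a, g) if b.ndim == 2 else g * a)
                else:
                    other._accum(a.T @ g)

        return self._make(value, (self, other), backward)

    # -- element-wise ----------------------------------------------------
    def tanh(self):
        value = np.tanh(self.value)

        def backward(g):
            self._accum(g * (1.0 - value**2))

        return self._make(value, (self,), backward)

    def relu(self):
        value = np.maximum(self.value, 0.0)

        def backward(g):
            self._accum(g * (self.value > 0.0))

        return self._make(value, (self,), backward)

    def softplus(self):
        # stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        value = np.maximum(self.value, 0.0) + np.log1p(np.exp(-np.abs(self.value)))

        def backward(g):
            self._accum(g * _sigmoid(self.value))

        return self._make(value, (self,), backward)

    def exp(self):
        value = np.exp(self.value)

        def backward(g):
            self._accum(g * value)

        return self._make(value, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.value)

        return self._make(np.log(self.value), (self,), backward)

    def square(self):
        def backward(g):
            self._accum(g * 2.0 * self.value)

        return self._make(self.value**2, (self,), backward)

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        value = self.value.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape).copy())

        return self._make(value, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.value.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.value.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g):
            self._accum(g.T)

        return self._make(self.value.T, (self,), backward)


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(scores: Tensor) -> Tensor:
    """Max-shifted softmax over a 1-D score vector."""
    shift = scores - float(scores.value.max())
    e = shift.exp()
    return e / e.sum()


def bce_with_logits(logit: Tensor, y: float) -> Tensor:
    """Bernoulli negative log-likelihood in logit space.

    -log p(y | logit) = softplus(logit) - y * logit, stable for any scale.
    """
    return logit.softplus() - logit * float(y)
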