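"""Reverse-mode automatic differentiation on dense NumPy arrays.

This is a deliberately small tape-based autodiff engine covering exactly the
operations the association model needs: affine maps, propagation by constant
graph matrices, elementwise nonlinearities, reductions, concatenation and row
gathering. Everything is float64; gradients of broadcast operands are summed
back to the operand shape. Only 1-D/2-D arrays are exercised.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- introspection -------------------------------------------------
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

    # -- graph bookkeeping ---------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar output, accumulating into ``.grad``."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be moderately deep
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        for node in topo:
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
        self.grad = self.grad + np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = _node(self.data + other.data, (self, other))

        def backward(grad):
            if self.requires_grad:
                self.grad += _unbroadcast(grad, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(grad, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = _node(self.data * other.data, (self, other))

        def backward(grad):
            if self.requires_grad:
                self.grad += _unbroadcast(grad * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(grad * self.data, other.data.shape)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return self * other**-1.0
        return self * (1.0 / other)

    def __pow__(self, exponent: float) -> "Tensor":
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        out = _node(self.data**exponent, (self,))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad * exponent * self.data ** (exponent - 1.0)

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = _node(self.data @ other.data, (self, other))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ grad

        out._backward = backward
        return out

    # -- elementwise nonlinearities --------------------------------------
    def relu(self) -> "Tensor":
        out = _node(np.maximum(self.data, 0.0), (self,))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad * (self.data > 0.0)

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        value = np.exp(self.data)
        out = _node(value, (self,))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad * value

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = _node(np.log(self.data), (self,))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad / self.data

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        value = expit(self.data)
        out = _node(value, (self,))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad * value * (1.0 - value)

        out._backward = backward
        return out

    def softplus(self) -> "Tensor":
        # log(1 + exp(x)), computed stably; derivative is the logistic.
        out = _node(np.logaddexp(0.0, self.data), (self,))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad * expit(self.data)

        out._backward = backward
        return out

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(grad):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self.grad += np.broadcast_to(grad, self.data.shape)

        out._backward = backward
        return out

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def rows(self, index) -> "Tensor":
        """Gather rows by integer index (duplicates allowed)."""
        index = np.asarray(index, dtype=np.intp)
        out = _node(self.data[index], (self,))

        def backward(grad):
            if self.requires_grad:
                np.add.at(self.grad, index, grad)

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = _node(self.data.reshape(*shape), (self,))

        def backward(grad):
            if self.requires_grad:
                self.grad += grad.reshape(self.data.shape)

        out._backward = backward
        return out


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    grad_parents = tuple(p for p in parents if p.requires_grad)
    if grad_parents:
        out.requires_grad = True
        out._parents = grad_parents
    return out


def cat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for tensor, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if tensor.requires_grad:
                slicer = [slice(None)] * grad.ndim
                slicer[axis] = slice(start, stop)
                tensor.grad += grad[tuple(slicer)]

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors (full-batch use)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        bias1 = 1.0 - self.beta1**self._t
        bias2 = 1.0 - self.beta2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
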