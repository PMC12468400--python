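"""Compact reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the residual VAE and the gradient-based
attribution methods need: affine maps, elementwise arithmetic, ReLU,
exp/log/sqrt, reductions, and a numerically stable log-softmax. Gradients
propagate to any leaf marked ``requires_grad`` — model parameters during
training, the input matrix during attribution.

Broadcasting follows numpy; backward passes sum gradients over broadcast
axes so shapes always round-trip.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def _child(self, data, parents):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(p for p in parents if p.requires_grad)
        return out

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = self._child(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._child(-self.data, (self,))
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._child(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._child(self.data / other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = self._child(self.data @ other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ elementwise
    def relu(self):
        mask = self.data > 0
        out = self._child(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    def exp(self):
        val = np.exp(self.data)
        out = self._child(val, (self,))
        out._backward = lambda g: self._accum(g * val) if self.requires_grad else None
        return out

    def log(self):
        out = self._child(np.log(self.data), (self,))
        out._backward = (
            lambda g: self._accum(g / self.data) if self.requires_grad else None
        )
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = self._child(val, (self,))
        out._backward = (
            lambda g: self._accum(g * 0.5 / val) if self.requires_grad else None
        )
        return out

    def square(self):
        return self * self

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (straight-through
        inside)."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = self._child(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g, dtype=np.float64)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- softmax
    def log_softmax(self):
        """Row-wise log-softmax, stabilised by a detached row max."""
        m = self.data.max(axis=-1, keepdims=True)
        shifted = self - Tensor(m)
        return shifted - shifted.exp().sum(axis=-1, keepdims=True).log()

    # --------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def concat_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0 (used for minibatch assembly)."""
    data = np.concatenate([t.data for t in tensors], axis=0)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    out._parents = tuple(t for t in tensors if t.requires_grad)

    def backward(g):
        start = 0
        for t in tensors:
            n = t.data.shape[0]
            if t.requires_grad:
                t._accum(g[start : start + n])
            start += n

    out._backward = backward
    return out
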