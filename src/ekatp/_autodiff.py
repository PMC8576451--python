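"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the EKATP training objective needs:
dense affine layers, tanh/relu nonlinearities, column slicing and
concatenation (for the structured companion-operator application),
elementwise arithmetic with numpy-style broadcasting, and mean-square
reductions.  Gradients are accumulated by a topological sweep over the
recorded computation graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tanh", "relu", "concat", "mse"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operations --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(-grad)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(grad):
            # handled layouts: (B,m)@(m,p), (B,m)@(m,), (m,)@(m,)
            if self.requires_grad:
                if other.data.ndim == 2:
                    g = grad if grad.ndim == 2 else grad[None, :]
                    d = g @ other.data.T
                    self._accumulate(d if self.data.ndim == 2 else d.ravel())
                else:
                    self._accumulate(np.multiply.outer(grad, other.data))
            if other.requires_grad:
                if self.data.ndim == 2:
                    g = grad if grad.ndim == 2 else grad[:, None]
                    d = self.data.T @ g
                    other._accumulate(d if other.data.ndim == 2 else d.ravel())
                elif other.data.ndim == 2:  # (m,) @ (m,p)
                    other._accumulate(np.multiply.outer(self.data, grad))
                else:
                    other._accumulate(grad * self.data)

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = grad  # basic (slice) indexing only
                self._accumulate(full)

        out._backward = backward
        return out

    def sum(self):
        out = Tensor(self.data.sum(), _parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(grad, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(grad / n, self.data.shape).copy())

        out._backward = backward
        return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, _parents=(x,))

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * (1.0 - y * y))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * (x.data > 0))

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(sl)])

    out._backward = backward
    return out


def mse(a: Tensor, b: Tensor) -> Tensor:
    """Mean squared error over all elements (the ‖·‖_MSE norm)."""
    d = a - b
    return (d * d).mean()
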