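"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the density-estimation networks
in this package: broadcasting arithmetic, matmul, pointwise nonlinearities,
reductions, slicing, gather, concatenation and cumulative sums.  Gradients
are accumulated by walking the tape in reverse topological order.  The
engine is deliberately small; correctness is asserted against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "where", "gather", "sigmoid", "softplus", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (),
                      backward=backward if req else None)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return self._make(out_data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside the interval."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)
        return self._make(out_data, (self,), lambda g: (g * mask,))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum(self, axis: int):
        out_data = np.cumsum(self.data, axis=axis)

        def backward(g):
            return (np.flip(np.cumsum(np.flip(g, axis), axis), axis),)

        return self._make(out_data, (self,), backward)

    # -- shaping ---------------------------------------------------------
    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(self.data.shape),))

    # -- backward pass ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad += g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            # leaves with requires_grad but also having parents do not occur
        # store gradient on the root too, if it is a leaf
        return None


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def where(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select between two tensors with a constant boolean mask."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        return (
            _unbroadcast(np.where(mask, g, 0.0), a.data.shape),
            _unbroadcast(np.where(mask, 0.0, g), b.data.shape),
        )

    return Tensor._make(out_data, (a, b), backward)


def gather(t: Tensor, idx: np.ndarray, axis: int = -1) -> Tensor:
    """``np.take_along_axis`` with scatter-add gradient; ``idx`` is constant."""
    out_data = np.take_along_axis(t.data, idx, axis=axis)
    ax = axis % t.data.ndim

    def backward(g):
        full = np.zeros_like(t.data)
        fancy = tuple(
            idx if d == ax else np.arange(t.data.shape[d]).reshape(
                [-1 if k == d else 1 for k in range(t.data.ndim)]
            )
            for d in range(t.data.ndim)
        )
        np.add.at(full, fancy, g)
        return (full,)

    return Tensor._make(out_data, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-t.data))
    return Tensor._make(out_data, (t,), lambda g: (g * out_data * (1 - out_data),))


def softplus(t: Tensor) -> Tensor:
    out_data = np.logaddexp(0.0, t.data)
    sig = 1.0 / (1.0 + np.exp(-t.data))
    return Tensor._make(out_data, (t,), lambda g: (g * sig,))


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - np.max(t.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
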