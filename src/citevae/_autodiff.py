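"""Minimal vectorized reverse-mode automatic differentiation.

The encoder/decoder networks in this package are small multilayer
perceptrons whose losses are built from a handful of primitives
(affine maps, elementwise transcendentals, log-gamma, reductions).
This module provides exactly those primitives on numpy arrays, with
gradients checked against finite differences in the test suite.

Broadcasting follows numpy semantics; gradients of broadcast operands
are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __sub__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)

        return Tensor._node(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor._lift(other) - self

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __neg__(self):
        def backward(g):
            return (-g,)

        return Tensor._node(-self.data, (self,), backward)

    def __pow__(self, p: float):
        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._node(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return Tensor._node(self.data @ other.data, (self, other), backward)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g_ = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_, self.shape).copy(),)

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autograd --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS: graphs can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if node.requires_grad and node._backward is None and g is not None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if parent._backward is None:  # leaf
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg


# -- elementwise functions ----------------------------------------------


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g):
        return (g * out_data,)

    return Tensor._node(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        return (g / x.data,)

    return Tensor._node(np.log(x.data), (x,), backward)


def relu(x: Tensor) -> Tensor:
    def backward(g):
        return (g * (x.data > 0),)

    return Tensor._node(np.maximum(x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = expit(x.data)

    def backward(g):
        return (g * out_data * (1.0 - out_data),)

    return Tensor._node(out_data, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    # log(1 + e^x), stable for large |x|
    out_data = np.logaddexp(0.0, x.data)

    def backward(g):
        return (g * expit(x.data),)

    return Tensor._node(out_data, (x,), backward)


def lgamma(x: Tensor) -> Tensor:
    def backward(g):
        return (g * digamma(x.data),)

    return Tensor._node(gammaln(x.data), (x,), backward)


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """log(e^a + e^b), elementwise and numerically stable."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.logaddexp(a.data, b.data)

    def backward(g):
        wa = expit(a.data - b.data)  # e^a / (e^a + e^b)
        return _unbroadcast(g * wa, a.shape), _unbroadcast(g * (1.0 - wa), b.shape)

    return Tensor._node(out_data, (a, b), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; straight-through gradient inside the bounds, zero outside."""
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        return (g * mask,)

    return Tensor._node(np.clip(x.data, lo, hi), (x,), backward)


# -- optimizer -----------------------------------------------------------


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
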