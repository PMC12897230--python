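"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery to express and train a small windowed-attention
restoration network on a CPU: tensors with recorded parents, broadcasting-
aware elementwise ops, batched matmul, reshape/transpose, softmax, layer
normalisation, tanh/sigmoid/GELU, reductions, and an Adam optimiser.  Every
analytic gradient here is checked against central finite differences in the
test suite.

Arrays are kept in whatever float dtype they are given (the denoiser uses
float32 for speed; gradient-check tests use float64).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam"]


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    def _make(self, data, parents, backward):
        out = Tensor(data, parents=parents, backward=backward)
        return out

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other, self.data.dtype)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other, self.data.dtype))

    def __rsub__(self, other):
        return _wrap(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _wrap(other, self.data.dtype)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product with NumPy broadcasting on leading axes."""
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.data.shape), _unbroadcast(gb, other.data.shape)

        out._backward = backward
        return out

    __matmul__ = matmul

    # ---- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: (g.reshape(orig),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    # ---- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---- nonlinearities ------------------------------------------------------

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))
        out._backward = lambda g: (g * np.sign(self.data),)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def gelu(self):
        """GELU with the tanh approximation (as used in transformer MLPs)."""
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor(y, (self,))

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            return (g * dy,)

        out._backward = backward
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, (self,))

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        out._backward = backward
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gamma.data + beta.data, (self, gamma, beta))
        n = x.shape[-1]

        def backward(g):
            dxhat = g * gamma.data
            dx = inv / n * (n * dxhat - dxhat.sum(-1, keepdims=True) - xhat * (dxhat * xhat).sum(-1, keepdims=True))
            dgamma = _unbroadcast(g * xhat, gamma.data.shape)
            dbeta = _unbroadcast(g, beta.data.shape)
            return dx, dgamma, dbeta

        out._backward = backward
        return out

    # ---- backward pass ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS post-order
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node.parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                if node.requires_grad:
                    topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node.parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g


def _wrap(value, dtype) -> Tensor:
    if isinstance(value, Tensor):
        return value
    return Tensor(np.asarray(value, dtype=dtype))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to the original operand shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def constant(data) -> Tensor:
    return Tensor(np.asarray(data))


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


class Adam:
    """Adam with fixed hyperparameters over a dict of named parameters."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
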