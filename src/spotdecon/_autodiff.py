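"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based engine sized for the models in this package: dense
linear layers, softmax decoders, closed-form KL terms and reparameterized
sampling (Gaussian pathwise, Gamma/Dirichlet implicit).  Everything is
float64 and deterministic given a :class:`numpy.random.Generator`.

Only the primitives the model needs are provided; gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as sps

__all__ = [
    "Tensor",
    "as_tensor",
    "lgamma",
    "digamma",
    "softplus",
    "relu",
    "softmax",
    "log_softmax",
    "gamma_rsample",
    "normal_rsample",
    "Adam",
    "kaiming_normal",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (),
                 backward: Callable[[np.ndarray], None] | None = None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- graph construction --------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def back(g):
            self._accumulate(g)
            other._accumulate(g)
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def back(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        def back(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data ** 2)
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def back(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        out._backward = back
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = back
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- elementwise transcendentals ------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / val)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def lgamma(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = Tensor(sps.gammaln(t.data), parents=(t,))
    out._backward = lambda g: t._accumulate(g * sps.digamma(t.data))
    return out


def digamma(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = Tensor(sps.digamma(t.data), parents=(t,))
    out._backward = lambda g: t._accumulate(g * sps.polygamma(1, t.data))
    return out


def softplus(t: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable."""
    t = as_tensor(t)
    val = np.logaddexp(0.0, t.data)
    out = Tensor(val, parents=(t,))
    out._backward = lambda g: t._accumulate(g * sps.expit(t.data))
    return out


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = (t.data > 0).astype(np.float64)
    out = Tensor(t.data * mask, parents=(t,))
    out._backward = lambda g: t._accumulate(g * mask)
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(t.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    s = t - shift
    return s - s.exp().sum(axis=axis, keepdims=True).log()


def normal_rsample(mu: Tensor, var: Tensor, rng: np.random.Generator) -> Tensor:
    """Pathwise sample from N(mu, var) (var is a variance)."""
    eps = rng.standard_normal(np.broadcast_shapes(mu.shape, var.shape))
    return mu + var.sqrt() * eps


def gamma_rsample(alpha: Tensor, rng: np.random.Generator) -> Tensor:
    """Sample Gamma(alpha, 1) with implicit reparameterization gradients.

    The derivative of the sample w.r.t. the shape parameter is
    dz/da = -(dF(z; a)/da) / pdf(z; a); dF/da is evaluated by a central
    finite difference of the regularized incomplete gamma function.
    """
    alpha = as_tensor(alpha)
    a = alpha.data
    z = np.maximum(rng.standard_gamma(a), 1e-12)
    out = Tensor(z, parents=(alpha,))

    def back(g):
        h = 1e-5 * np.maximum(a, 1e-2)
        dFda = (sps.gammainc(a + h, z) - sps.gammainc(a - h, z)) / (2.0 * h)
        log_pdf = (a - 1.0) * np.log(z) - z - sps.gammaln(a)
        pdf = np.maximum(np.exp(log_pdf), 1e-300)
        alpha._accumulate(g * (-dFda / pdf))

    out._backward = back
    return out


def kaiming_normal(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """He-normal weight init for a (fan_in, fan_out) layer."""
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


class Adam:
    """Adam with optional multiplicative (exponential) learning-rate decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_decay: float = 1.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def decay_lr(self) -> None:
        self.lr *= self.lr_decay
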