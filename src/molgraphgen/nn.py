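"""Reverse-mode automatic differentiation over NumPy arrays.

The decoding policies are small graph-convolutional networks that have to be
trained with gradient descent.  This module provides the machinery they are
built from: a :class:`Tensor` holding a ``float64`` array plus the backward
closures needed for reverse-mode differentiation, a handful of layers
(:class:`Linear`, :class:`BatchNorm`, :class:`GRUCell`) and the :class:`Adam`
optimizer.  Everything is vectorized -- scalar graphs never enter Python loops
below the per-layer level -- which keeps desk-scale training runs in the
seconds-to-minutes range on a single CPU.

Only the operations the policy networks actually use are implemented.  All
arrays are ``float64``; broadcasting follows NumPy semantics, with gradients
summed back over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "add", "sub", "mul", "div", "neg", "matmul",
    "exp", "log", "tanh", "sigmoid", "relu", "power", "tsum", "tmean",
    "concat", "take", "embedding", "reshape", "log_softmax", "Linear",
    "BatchNorm", "GRUCell", "Adam", "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self._parents = parents
        self._grad_fn = grad_fn
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self.grad = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._grad_fn is None:
                continue
            grads = node._grad_fn(node.grad)
            for p, g in zip(node._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                if p.grad is None:
                    p.grad = np.zeros_like(p.data)
                p.grad += g

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise / binary ops ---------------------------------------------

def add(a, b):
    a, b = _t(a), _t(b)
    return Tensor(a.data + b.data, (a, b), lambda up: (
        _unbroadcast(up, a.data.shape), _unbroadcast(up, b.data.shape)))


def sub(a, b):
    a, b = _t(a), _t(b)
    return Tensor(a.data - b.data, (a, b), lambda up: (
        _unbroadcast(up, a.data.shape), _unbroadcast(-up, b.data.shape)))


def mul(a, b):
    a, b = _t(a), _t(b)
    return Tensor(a.data * b.data, (a, b), lambda up: (
        _unbroadcast(up * b.data, a.data.shape),
        _unbroadcast(up * a.data, b.data.shape)))


def div(a, b):
    a, b = _t(a), _t(b)
    return Tensor(a.data / b.data, (a, b), lambda up: (
        _unbroadcast(up / b.data, a.data.shape),
        _unbroadcast(-up * a.data / (b.data ** 2), b.data.shape)))


def neg(a):
    a = _t(a)
    return Tensor(-a.data, (a,), lambda up: (-up,))


def matmul(a, b):
    a, b = _t(a), _t(b)
    return Tensor(a.data @ b.data, (a, b), lambda up: (
        up @ b.data.T, a.data.T @ up))


def exp(a):
    a = _t(a)
    out = np.exp(a.data)
    return Tensor(out, (a,), lambda up: (up * out,))


def log(a):
    a = _t(a)
    return Tensor(np.log(a.data), (a,), lambda up: (up / a.data,))


def tanh(a):
    a = _t(a)
    out = np.tanh(a.data)
    return Tensor(out, (a,), lambda up: (up * (1.0 - out ** 2),))


def sigmoid(a):
    a = _t(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(out, (a,), lambda up: (up * out * (1.0 - out),))


def relu(a):
    a = _t(a)
    mask = a.data > 0
    return Tensor(a.data * mask, (a,), lambda up: (up * mask,))


def power(a, p: float):
    a = _t(a)
    return Tensor(a.data ** p, (a,),
                  lambda up: (up * p * a.data ** (p - 1.0),))


# -- reductions / reshaping -----------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _t(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def gf(up):
        if axis is None:
            return (np.broadcast_to(up, a.data.shape).copy(),)
        u = up if keepdims else np.expand_dims(up, axis)
        return (np.broadcast_to(u, a.data.shape).copy(),)

    return Tensor(out, (a,), gf)


def tmean(a, axis=None, keepdims=False):
    a = _t(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors, axis=0):
    tensors = [_t(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def gf(up):
        return tuple(np.split(up, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors), gf)


def reshape(a, shape):
    a = _t(a)
    return Tensor(a.data.reshape(shape), (a,),
                  lambda up: (up.reshape(a.data.shape),))


def getitem(a, key):
    a = _t(a)

    def gf(up):
        g = np.zeros_like(a.data)
        np.add.at(g, key, up)
        return (g,)

    return Tensor(a.data[key], (a,), gf)


def take(a, flat_indices):
    """Gather entries of the flattened tensor; returns a 1-D tensor."""
    a = _t(a)
    idx = np.asarray(flat_indices, dtype=np.intp)

    def gf(up):
        g = np.zeros(a.data.size)
        np.add.at(g, idx, up)
        return (g.reshape(a.data.shape),)

    return Tensor(a.data.reshape(-1)[idx], (a,), gf)


def embedding(table, indices):
    """Row lookup into a 2-D parameter table."""
    idx = np.asarray(indices, dtype=np.intp)

    def gf(up):
        g = np.zeros_like(table.data)
        np.add.at(g, idx, up)
        return (g,)

    return Tensor(table.data[idx], (table,), gf)


def log_softmax(a):
    """Log-softmax of a 1-D tensor (max-shifted for stability)."""
    a = _t(a)
    m = float(a.data.max())
    shifted = a - m
    return shifted - log(exp(shifted).sum())


# -- layers ----------------------------------------------------------------

def glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    scale = np.sqrt(2.0 / (shape[0] + shape[-1]))
    return rng.normal(0.0, scale, shape)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Parameter(glorot(rng, (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class BatchNorm:
    """Per-feature batch normalization over axis 0.

    Batch statistics during training; exponentially averaged running
    statistics at inference.  A batch here is the set of atoms of all graph
    states scored together, so single-atom batches are legal (epsilon keeps
    the variance positive).
    """

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
            xn = (x - mu) / power(var + self.eps, 0.5)
        else:
            xn = (x - self.running_mean[None, :]) * (
                1.0 / np.sqrt(self.running_var[None, :] + self.eps))
        return xn * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def buffers(self):
        return [self.running_mean, self.running_var]


class GRUCell:
    """Single gated recurrent unit layer (reset gate applied to ``h @ Un``)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.Wz = Parameter(glorot(rng, (n_in, n_hidden)))
        self.Uz = Parameter(glorot(rng, (n_hidden, n_hidden)))
        self.bz = Parameter(np.zeros(n_hidden))
        self.Wr = Parameter(glorot(rng, (n_in, n_hidden)))
        self.Ur = Parameter(glorot(rng, (n_hidden, n_hidden)))
        self.br = Parameter(np.zeros(n_hidden))
        self.Wn = Parameter(glorot(rng, (n_in, n_hidden)))
        self.Un = Parameter(glorot(rng, (n_hidden, n_hidden)))
        self.bn = Parameter(np.zeros(n_hidden))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = sigmoid(x @ self.Wz + h @ self.Uz + self.bz)
        r = sigmoid(x @ self.Wr + h @ self.Ur + self.br)
        n = tanh(x @ self.Wn + r * (h @ self.Un) + self.bn)
        return (1.0 - z) * n + z * h

    @property
    def params(self):
        return [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
                self.Wn, self.Un, self.bn]


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self.t)
            vhat = self._v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
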