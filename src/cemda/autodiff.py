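"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective composes linear projections, an MLP, a GRU unrolled
over short meta-path sequences, softmax attention (dense and segment-wise)
and log-likelihood losses.  This module provides exactly the operator set
needed to backpropagate through that computation graph, with full
broadcasting support, plus a Glorot initializer and an Adam optimizer.

Gradients are validated against central finite differences in the test
suite; keep any new operator covered by ``tests/test_autodiff.py``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter", "add", "mul", "matmul", "transpose",
    "relu", "sigmoid", "tanh", "exp", "log", "logsigmoid", "softmax",
    "concat", "take", "segment_sum", "col", "reshape", "sum_", "mean_",
    "glorot", "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents  # tuple of (Tensor, grad_fn)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, constant(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def backward(self):
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.grad is None:  # not on a path to the root
                continue
            for p, grad_fn in t.parents:
                if p.requires_grad:
                    c = _unbroadcast(grad_fn(t.grad), p.data.shape)
                    p.grad = c if p.grad is None else p.grad + c


def _wrap(x):
    return x if isinstance(x, Tensor) else constant(x)


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


# -- primitive operators ------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, ((a, lambda g: g), (b, lambda g: g)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data * b.data,
                  ((a, lambda g: g * b.data), (b, lambda g: g * a.data)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data / b.data,
                  ((a, lambda g: g / b.data),
                   (b, lambda g: -g * a.data / (b.data ** 2))))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data @ b.data,
                  ((a, lambda g: g @ b.data.T), (b, lambda g: a.data.T @ g)))


def transpose(a: Tensor) -> Tensor:
    return Tensor(a.data.T, ((a, lambda g: g.T),))


def relu(a: Tensor) -> Tensor:
    m = (a.data > 0).astype(np.float64)
    return Tensor(a.data * m, ((a, lambda g: g * m),))


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    return Tensor(s, ((a, lambda g: g * s * (1 - s)),))


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    return Tensor(t, ((a, lambda g: g * (1 - t * t)),))


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)
    return Tensor(e, ((a, lambda g: g * e),))


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), ((a, lambda g: g / a.data),))


def logsigmoid(a: Tensor) -> Tensor:
    """log(sigmoid(x)) = -softplus(-x), numerically stable."""
    x = a.data
    out = np.where(x >= 0, -np.log1p(np.exp(-x)), x - np.log1p(np.exp(x)))
    s = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    return Tensor(out, ((a, lambda g: g * (1 - s)),))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Softmax along `axis` with a stop-gradient max shift."""
    shift = constant(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return div(e, sum_(e, axis=axis, keepdims=True))


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def grad_fn(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.data.shape).copy()

    return Tensor(out, ((a, grad_fn),))


def mean_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), constant(1.0 / n))


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
        def grad_fn(g, lo=lo, hi=hi):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            return g[tuple(idx)]
        parents.append((t, grad_fn))
    return Tensor(out, tuple(parents))


def take(a: Tensor, indices) -> Tensor:
    """Gather rows (axis 0); gradient scatters with accumulation."""
    idx = np.asarray(indices)

    def grad_fn(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return out

    return Tensor(a.data[idx], ((a, grad_fn),))


def segment_sum(a: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of `a` into `num_segments` buckets; gradient gathers."""
    ids = np.asarray(segment_ids)
    out = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out, ids, a.data)
    return Tensor(out, ((a, lambda g: g[ids]),))


def col(a: Tensor, j: int) -> Tensor:
    """Column j of a 2-D tensor, kept as (n, 1)."""

    def grad_fn(g):
        out = np.zeros_like(a.data)
        out[:, j:j + 1] = g
        return out

    return Tensor(a.data[:, j:j + 1], ((a, grad_fn),))


def reshape(a: Tensor, shape) -> Tensor:
    return Tensor(a.data.reshape(shape),
                  ((a, lambda g: g.reshape(a.data.shape)),))


# -- initialisation and optimisation ------------------------------------

def glorot(rng: np.random.Generator, shape) -> np.ndarray:
    """Glorot-uniform initial values for a weight of the given shape."""
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
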