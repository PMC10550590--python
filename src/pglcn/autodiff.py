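"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the network and the explainer need:
elementwise arithmetic with broadcasting, matmul, relu/sigmoid/exp/log/abs,
reductions, reshape, row gather and segment-sum (the sparse primitives used
to evaluate the learned affinity over the support of the prior adjacency),
plus an Adam optimizer. Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "parameter", "constant", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # added leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # broadcast singleton axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached backward graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad=False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    def numpy(self) -> np.ndarray:
        return self.value

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += _unbroadcast(g, self.value.shape)

    def backward(self, grad=None):
        """Reverse-mode pass from this (typically scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.value) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.value)
            if other.requires_grad:
                other._accumulate(g * self.value)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.value / other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.value)
            if other.requires_grad:
                other._accumulate(-g * self.value / other.value**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.value**exponent, parents=(self,))
        out._backward = lambda g: self._accumulate(g * exponent * self.value ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.value.T)
            if other.requires_grad:
                other._accumulate(self.value.T @ g)

        out._backward = bwd
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self):
        out = Tensor(np.maximum(self.value, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.value > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.value))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.value)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.value), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.value)
        return out

    def abs(self):
        out = Tensor(np.abs(self.value), parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.value))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (projection)."""
        out = Tensor(np.clip(self.value, lo, hi), parents=(self,))
        inside = (self.value >= lo) & (self.value <= hi)
        out._backward = lambda g: self._accumulate(g * inside)
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.value.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, parents=(self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # --------------------------------------------------------- sparse helpers
    def take_rows(self, idx: np.ndarray):
        """Gather rows: out[k] = self[idx[k]]. idx may repeat."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.value[idx], parents=(self,))

        def bwd(g):
            acc = np.zeros_like(self.value)
            np.add.at(acc, idx, g)
            self._accumulate(acc)

        out._backward = bwd
        return out

    def segment_sum(self, seg_ids: np.ndarray, num_segments: int):
        """out[s] = sum over rows k with seg_ids[k] == s (scatter-add)."""
        seg_ids = np.asarray(seg_ids, dtype=np.intp)
        shape = (num_segments,) + self.value.shape[1:]
        acc = np.zeros(shape)
        np.add.at(acc, seg_ids, self.value)
        out = Tensor(acc, parents=(self,))
        out._backward = lambda g: self._accumulate(g[seg_ids])
        return out


def cat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def parameter(value, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Create a trainable tensor; with `rng`, `value` is a shape to init Gaussian."""
    if rng is not None:
        shape = value
        scale = scale if scale is not None else 1.0 / np.sqrt(max(1, np.prod(shape[:-1]) if len(shape) > 1 else shape[0]))
        value = rng.normal(0.0, scale, size=shape)
    return Tensor(np.asarray(value, dtype=np.float64), requires_grad=True)


def constant(value) -> Tensor:
    return Tensor(value)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
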