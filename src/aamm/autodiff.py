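"""Minimal reverse-mode automatic differentiation over numpy arrays.

The models in this package (a Gaussian-mixture VAE and a cross-attention
fusion classifier) are trained by gradient descent.  This module provides
the small tensor/graph machinery they need: a :class:`Tensor` wrapping a
numpy array, the differentiable primitives used by the models (matmul,
broadcast arithmetic, exp/log, reductions, softmax/log-sum-exp, slicing),
and nothing else.

Conventions
-----------
* A ``Tensor`` records its parents and a backward closure; ``backward()``
  runs a topological sweep accumulating ``grad`` arrays.
* Broadcasting follows numpy; gradients are summed back over broadcast
  axes (:func:`_unbroadcast`).
* The functional helpers (:func:`exp`, :func:`softmax`, ...) dispatch on
  input type, so the same model code can run on plain numpy arrays (pure
  inference, no graph) or on Tensors (training).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "exp",
    "log",
    "tanh",
    "relu",
    "sum_",
    "mean_",
    "softmax",
    "log_softmax",
    "logsumexp",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` so it has ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray, fresh: bool = False) -> None:
        """Accumulate a gradient contribution.

        ``fresh=True`` promises ``g`` is a newly allocated array not shared
        with any other node, so it can be adopted without a copy.
        """
        g = np.asarray(g)
        reduced = g.shape != self.data.shape
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            if (fresh or reduced) and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def zero_grad(self) -> None:
        self.grad = None

    def _coerce(self, other) -> "Tensor":
        """Wrap ``other``; python scalars adopt this tensor's dtype so a
        float32 graph is not silently upcast to float64."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def back():
            self._accum(out.grad)
            other._accum(out.grad)

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def back():
            self._accum(out.grad * other.data, fresh=True)
            other._accum(out.grad * self.data, fresh=True)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def back():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / other.data**2)

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def back():
            self._accum(out.grad @ other.data.T, fresh=True)
            other._accum(self.data.T @ out.grad, fresh=True)

        out._backward = back
        return out

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda: self._accum(out.grad * (1.0 - out.data**2))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _parents=(self,))
        out._backward = lambda: self._accum(out.grad * mask)
        return out

    # -- reductions and shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def back():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _parents=(self,))
        out._backward = lambda: self._accum(out.grad.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def back():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = back
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# Functional helpers dispatching on numpy arrays vs Tensors.
# ---------------------------------------------------------------------------

def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def exp(x):
    return x.exp() if _is_t(x) else np.exp(x)


def log(x):
    return x.log() if _is_t(x) else np.log(x)


def tanh(x):
    return x.tanh() if _is_t(x) else np.tanh(x)


def relu(x):
    return x.relu() if _is_t(x) else np.maximum(x, 0.0)


def sum_(x, axis=None, keepdims=False):
    return x.sum(axis=axis, keepdims=keepdims) if _is_t(x) else np.sum(
        x, axis=axis, keepdims=keepdims
    )


def mean_(x, axis=None, keepdims=False):
    return x.mean(axis=axis, keepdims=keepdims) if _is_t(x) else np.mean(
        x, axis=axis, keepdims=keepdims
    )


def logsumexp(x, axis=-1, keepdims: bool = False):
    """Numerically stable log-sum-exp; the max shift is treated as constant."""
    xv = x.data if _is_t(x) else x
    shift = np.max(xv, axis=axis, keepdims=True)
    out = log(sum_(exp(x - shift), axis=axis, keepdims=True)) + shift
    if not keepdims:
        target = list(xv.shape)
        target.pop(axis % len(target))
        out = out.reshape(tuple(target))
    return out


def softmax(x, axis=-1):
    xv = x.data if _is_t(x) else x
    shift = np.max(xv, axis=axis, keepdims=True)
    e = exp(x - shift)
    return e / sum_(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    return x - logsumexp(x, axis=axis, keepdims=True)


def concat(xs, axis=0):
    if not any(_is_t(x) for x in xs):
        return np.concatenate(xs, axis=axis)
    xs = [as_tensor(x) for x in xs]
    out = Tensor(np.concatenate([x.data for x in xs], axis=axis), _parents=tuple(xs))

    def back():
        start = 0
        for x in xs:
            n = x.data.shape[axis]
            sl = [slice(None)] * out.data.ndim
            sl[axis] = slice(start, start + n)
            x._accum(out.grad[tuple(sl)])
            start += n

    out._backward = back
    return out
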