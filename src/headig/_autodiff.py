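"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the transformer encoder needs (broadcasting
arithmetic, batched matmul, exp/log/tanh, reductions, reshaping, slicing)
and gradient retrieval at *any* intermediate node, which is what layer-wise
attribution requires: after one backward pass from a scalar score,
``node.grad`` is available for the embedding input and for every recorded
multi-head self-attention output.

Design notes:
- ``requires_grad`` propagates through ops; backward closures skip parents
  that do not require gradients. Attribution passes therefore never pay for
  weight gradients (the parameters are constants there), which roughly
  halves the cost of a backward pass.
- Gradient accumulation is alias-safe without defensive copies: the first
  contribution may alias a consumer's buffer, later contributions allocate
  a fresh sum (``grad = grad + g``) instead of mutating in place.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "gelu", "softmax", "layer_norm"]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad", "name")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        requires_grad: bool | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward: Callable[[np.ndarray], None] | None = None
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        self.requires_grad = requires_grad
        self.name = name

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g  # may alias a consumer's buffer; never mutated
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        if not self.requires_grad:
            raise RuntimeError("backward() from a tensor that requires no grad")
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))
        out_data = out.data  # captured by value: avoids a gc cycle via out

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * out_data / other.data, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:  # inner product
                if self.requires_grad:
                    self._accumulate(g * b)
                if other.requires_grad:
                    other._accumulate(g * a)
                return
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out_data = out.data
        out._backward = lambda g: self._accumulate(g * out_data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out_data = out.data
        out._backward = lambda g: self._accumulate(g * (1.0 - out_data**2))
        return out

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(
            np.ascontiguousarray(g).reshape(self.data.shape)
        )
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"


# -- composite ops used by the encoder -------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is detached (gradient-free)."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def gelu(x: Tensor) -> Tensor:
    """GELU (tanh approximation) — smooth, which keeps IG quadrature accurate."""
    inner = (x + (x * x * x) * 0.044715) * _SQRT_2_OVER_PI
    return x * 0.5 * (inner.tanh() + 1.0)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gamma + beta
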