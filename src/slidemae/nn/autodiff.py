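"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training loops in this package optimise a small transformer encoder, so
the engine only implements the operations that model needs: broadcasting
arithmetic, batched matrix products, reductions, row gathers (for learnable
positional tables), softmax with an additive mask, GELU and layer
normalisation.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which topologically sorts the recorded tape.

Every op checks gradients against finite differences in the test-suite; keep
new ops covered there.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "concat", "gelu", "layer_norm", "masked_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """A numpy array with a gradient tape.

    Parameters with ``requires_grad=True`` accumulate into ``.grad``;
    intermediate results propagate regardless so the tape stays connected.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out._prev = tuple(parents)
        out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(
                _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            )
            other._accum(
                _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
            )

        return self._make(self.data @ other.data, (self, other), bw)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def take(self, indices, axis: int = 0):
        """Gather rows along `axis`; scatter-add on the way back."""
        indices = np.asarray(indices)

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, (slice(None),) * axis + (indices,), g)
            self._accum(acc)

        return self._make(np.take(self.data, indices, axis=axis), (self,), bw)

    # -- reductions & pointwise -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g / (2.0 * out_data))

        return self._make(out_data, (self,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._prev = tuple(tensors)
    out._backward = bw
    return out


_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """GELU activation (tanh approximation)."""
    u = _SQRT_2_OVER_PI * (x.data + 0.044715 * x.data**3)
    t = np.tanh(u)
    out_data = 0.5 * x.data * (1.0 + t)

    def bw(g):
        du = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x.data**2)
        dgelu = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t**2) * du
        x._accum(g * dgelu)

    out = Tensor(out_data)
    out._prev = (x,)
    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance, then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return xc * inv * gain + bias


def masked_softmax(logits: Tensor, valid: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to ``valid`` keys.

    Invalid positions get exactly zero probability; each row renormalises
    over its valid keys.  `valid` broadcasts against `logits`.
    """
    valid = np.broadcast_to(np.asarray(valid, dtype=bool), logits.shape)
    z = np.where(valid, logits.data, -np.inf)
    m = z.max(axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)  # rows with no valid key stay all-zero
    e = np.exp(z - m)
    e = np.where(valid, e, 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    s = e / np.where(denom == 0.0, 1.0, denom)

    def bw(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        logits._accum(s * (g - dot))

    out = Tensor(s)
    out._prev = (logits,)
    out._backward = bw
    return out
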