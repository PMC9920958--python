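"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing it;
``backward()`` walks the graph in reverse topological order accumulating
``grad`` arrays. The op set is exactly what the transformer encoder and the
tabular GAN need: broadcast arithmetic, batched matmul, reshape/transpose/
slicing, reductions, the usual activations, fused softmax / layer-norm /
embedding-lookup, and fused classification losses.

Gradient correctness is enforced by finite-difference checks in the test
suite; keep any new op covered there.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        if isinstance(other, (int, float)):  # weak scalar: no dtype upcast
            out_data = self.data + other

            def bw_s(g):
                self._accum(g)

            return Tensor._make(out_data, (self,), bw_s)
        other = self._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out_data = self.data * other

            def bw_s(g):
                self._accum(g * other)

            return Tensor._make(out_data, (self,), bw_s)
        other = self._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("tensor/tensor division is not used; multiply by inverse")
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        return Tensor._make(out_data, (self, other), bw)

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------- activations
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bw(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        x = self.data
        inv_sqrt2pi = 0.3989422804014327  # 1/sqrt(2*pi), kept a python float
        phi = np.exp(-0.5 * x**2) * inv_sqrt2pi
        cdf = 0.5 * (1.0 + erf(x * 0.7071067811865476))
        out_data = (x * cdf).astype(x.dtype)

        def bw(g):
            self._accum(g * (cdf + x * phi).astype(x.dtype))

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), bw)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, bw)


# --------------------------------------------------------------- fused ops
def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Gather rows of ``table`` (V, H) at integer ``ids`` (...,) -> (..., H)."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids.ravel(), g.reshape(-1, g.shape[-1]))
        table._accum(full)

    return Tensor._make(out_data, (table,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-12) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def bw(g):
        H = x.data.shape[-1]
        gxhat = g * gamma.data
        # d/dx of (x - mu) / sqrt(var + eps)
        dx = inv * (
            gxhat
            - gxhat.mean(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True)
        )
        x._accum(dx)
        red = tuple(range(g.ndim - 1))
        gamma._accum((g * xhat).sum(axis=red))
        beta._accum(g.sum(axis=red))

    return Tensor._make(out_data, (x, gamma, beta), bw)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (B, C) logits against int labels (B,)."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    B = logits.data.shape[0]
    out_data = np.asarray(-logp[np.arange(B), labels].mean(), dtype=logits.data.dtype)

    def bw(g):
        p = np.exp(logp)
        p[np.arange(B), labels] -= 1.0
        logits._accum(g * p / B)

    return Tensor._make(out_data, (logits,), bw)


def softmax_cross_entropy_probs(logits: Tensor, target_probs: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, C) logits against full target distributions."""
    t = np.asarray(target_probs)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    B = logits.data.shape[0]
    out_data = np.asarray(-(t * logp).sum(axis=-1).mean(), dtype=logits.data.dtype)

    def bw(g):
        p = np.exp(logp)
        logits._accum(g * (p * t.sum(axis=-1, keepdims=True) - t) / B)

    return Tensor._make(out_data, (logits,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    t = np.asarray(targets)
    x = logits.data
    # log(1 + exp(-|x|)) + max(x, 0) - x*t
    out = np.logaddexp(0.0, -np.abs(x)) + np.maximum(x, 0.0) - x * t
    out_data = np.asarray(out.mean(), dtype=x.dtype)

    def bw(g):
        sig = 1.0 / (1.0 + np.exp(-x))
        logits._accum(g * (sig - t) / x.size)

    return Tensor._make(out_data, (logits,), bw)
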