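"""Minimal reverse-mode automatic differentiation on numpy arrays.

The encoder in this package is small (two to twelve layers, hidden sizes in
the tens to hundreds), so a compact tape-based autograd over float64 numpy
arrays is sufficient to train it on a CPU.  Only the operations the model
needs are provided: broadcasting arithmetic, batched matmul, embedding
lookup, layer normalisation, exact (erf) GELU, sigmoid, additive-mask
softmax with an all-masked-row -> zero-row convention, dropout, and a
softmax cross-entropy head.

Gradients of every op are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "matmul", "embedding", "layer_norm", "gelu", "sigmoid",
           "masked_softmax", "dropout", "cross_entropy", "take_row", "concat_last"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; seeds with ones if no grad given."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        return matmul(self, self._lift(other))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = bwd
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup `table[ids]`; scatter-add gradient into the table."""
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], parents=(table,))

    def bwd(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate(acc)

    out._backward = bwd
    return out


def take_row(x: Tensor, index: int) -> Tensor:
    """Select one position along axis 1 of a (B, n, d) tensor -> (B, d)."""
    out = Tensor(x.data[:, index, :], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, index, :] = g
            x._accumulate(full)

    out._backward = bwd
    return out


def concat_last(parts: list[Tensor]) -> Tensor:
    """Concatenate along the last axis."""
    out = Tensor(np.concatenate([p.data for p in parts], axis=-1), parents=tuple(parts))
    sizes = [p.data.shape[-1] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                p._accumulate(g[..., lo:hi])

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact GELU: x * Phi(x) with the Gaussian CDF via erf."""
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out = Tensor(x.data * phi, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
            x._accumulate(g * (phi + x.data * pdf))

    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-12) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gx - m1 - xhat * m2))

    out._backward = bwd
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis after adding an additive 0/-inf mask.

    Rows whose mask is -inf everywhere have no admissible support; they are
    returned as all-zero rows (and carry zero gradient) rather than NaN.
    """
    z = scores.data + mask
    zmax = np.max(z, axis=-1, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)
    e = np.exp(z - zmax)
    tot = e.sum(axis=-1, keepdims=True)
    p = np.divide(e, tot, out=np.zeros_like(e), where=tot > 0)
    out = Tensor(p, parents=(scores,))

    def bwd(g):
        if scores.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            scores._accumulate(p * (g - dot))

    out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    out = Tensor(x.data * keep, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    out._backward = bwd
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (B, C) logits against integer labels."""
    labels = np.asarray(labels)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            grad = np.exp(logp)
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(g * grad / n)

    out._backward = bwd
    return out
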