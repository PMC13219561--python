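"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains only small models (low-rank adapter branches, a fusion
module and a linear head on top of a frozen transformer), so a compact tensor
autograd core is sufficient: dynamic graph, define-by-run, float64 throughout.
Gradients are accumulated into ``Tensor.grad`` by :func:`backward`.

Only the operations the model zoo needs are implemented: broadcasting
arithmetic, (batched) matmul, reductions, softmax/logsumexp, erf (for GELU),
leaky ReLU, reshaping, slicing and concatenation.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference / probing)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad}{tag})"

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    # ---------------------------------------------------------------- engine
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*tensors: Tensor) -> bool:
    if not _GRAD_ENABLED:
        return False
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ------------------------------------------------------------------ arithmetic
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(g):
        return (
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        )

    return _make(data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def bw(g):
        return (
            (a, _unbroadcast(g / b.data, a.shape)),
            (b, _unbroadcast(-g * a.data / (b.data**2), b.shape)),
        )

    return _make(data, (a, b), bw)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data**exponent

    def bw(g):
        return ((a, g * exponent * a.data ** (exponent - 1)),)

    return _make(data, (a,), bw)


def matmul(a, b) -> Tensor:
    """Matrix product with numpy's stacked-batch semantics."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(g):
        ga = gb = None
        if a.ndim == 1 and b.ndim == 1:  # inner product
            ga, gb = g * b.data, g * a.data
        elif b.ndim == 1:
            ga = np.expand_dims(g, -1) * b.data
            gb = _unbroadcast(
                (np.expand_dims(g, -1) * a.data).reshape(-1, a.shape[-1]).sum(0)
                if a.ndim > 2
                else a.data.T @ g,
                b.shape,
            )
        elif a.ndim == 1:
            ga = g @ np.swapaxes(b.data, -1, -2)
            ga = _unbroadcast(ga, a.shape)
            gb = np.outer(a.data, g) if b.ndim == 2 else np.expand_dims(a.data, -1) * np.expand_dims(g, -2)
            gb = _unbroadcast(gb, b.shape)
        else:
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
        return ((a, ga), (b, gb))

    return _make(data, (a, b), bw)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def bw(g):
        return ((a, g * data),)

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def bw(g):
        return ((a, g / a.data),)

    return _make(data, (a,), bw)


def erf(a) -> Tensor:
    a = _as_tensor(a)
    data = _erf(a.data)

    def bw(g):
        return ((a, g * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data**2)),)

    return _make(data, (a,), bw)


def leaky_relu(a, negative_slope: float = 0.1) -> Tensor:
    a = _as_tensor(a)
    data = np.where(a.data >= 0, a.data, negative_slope * a.data)

    def bw(g):
        return ((a, g * np.where(a.data >= 0, 1.0, negative_slope)),)

    return _make(data, (a,), bw)


# ------------------------------------------------------------------ reductions
def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.shape).copy()),)

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        inner = (g * data).sum(axis=axis, keepdims=True)
        return ((a, data * (g - inner)),)

    return _make(data, (a,), bw)


def logsumexp(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e.sum(axis=axis, keepdims=True)
    data = (m + np.log(s))
    soft = e / s
    if not keepdims:
        data = data.squeeze(axis)

    def bw(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, g * soft),)

    return _make(data, (a,), bw)


# --------------------------------------------------------------------- shapes
def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def bw(g):
        return ((a, g.reshape(a.shape)),)

    return _make(data, (a,), bw)


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)

    def bw(g):
        inv = None if axes is None else np.argsort(axes)
        return ((a, g.transpose(inv)),)

    return _make(data, (a,), bw)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]

    def bw(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return ((a, out),)

    return _make(data, (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(ts, pieces))

    return _make(data, ts, bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    expanded = [reshape(t, t.shape[:axis] + (1,) + t.shape[axis:]) for t in ts]
    return concat(expanded, axis=axis)


# ------------------------------------------------------------------ composites
def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """``x @ weight.T + bias`` with weight shaped [out, in]."""
    out = matmul(x, transpose(weight))
    if bias is not None:
        out = add(out, bias)
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    return mul(mul(x, 0.5), add(erf(mul(x, 1.0 / np.sqrt(2.0))), 1.0))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = tmean(x, axis=-1, keepdims=True)
    centered = x - mu
    var = tmean(mul(centered, centered), axis=-1, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return add(mul(mul(centered, inv), gamma), beta)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """x / (||x||_2 + eps); the additive guard keeps zero vectors at zero."""
    norm = power(tsum(mul(x, x), axis=axis, keepdims=True), 0.5)
    return div(x, add(norm, eps))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax logits."""
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.shape[0]
    lse = logsumexp(logits, axis=-1)
    picked = getitem(logits, (np.arange(n), labels))
    return tmean(lse - picked)
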