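"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the model needs: dense/sparse matrix
products, elementwise nonlinearities, stable log-sigmoid building blocks,
row softmax, layer normalization, dropout, gather/segment-sum (for
attention over edges), plus ``Linear`` layers, an AdamW optimizer and an
exponential-moving-average tracker.  Gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "AdamW",
    "EMA",
    "concat",
    "spmm",
    "gather_rows",
    "segment_sum",
    "dropout",
]


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
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        # `own=True` promises g is a fresh array no other node will reuse,
        # letting us adopt it without a defensive copy.
        if self.grad is None:
            self.grad = g if own else np.array(g, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            # python scalars stay weakly typed: no float64 upcast of the array
            out = _node(self.data + other, (self,))
            out._backward = lambda g: self._accumulate(g)
            return out
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape),
                                 own=g.shape != self.data.shape)
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape),
                                  own=g.shape != other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g, own=True)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = _node(self.data * other, (self,))
            out._backward = lambda g: self._accumulate(g * other, own=True)
            return out
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape),
                                 own=True)
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape),
                                  own=True)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape),
                                 own=True)
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2,
                                 other.data.shape), own=True)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T, own=True)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g, own=True)

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            if isinstance(idx, tuple) and all(isinstance(s, slice) for s in idx):
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full, own=True)

        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = _node(np.maximum(self.data, 0), (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0), own=True)
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = _node(np.where(self.data > 0, self.data, slope * self.data), (self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, slope), own=True)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * (1 - y**2), own=True)
        return out

    def sigmoid(self):
        y = _sigmoid(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * y * (1 - y), own=True)
        return out

    def softplus(self):
        """log(1 + exp(x)), computed stably; -softplus(-x) is log sigmoid."""
        y = np.logaddexp(0.0, self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * _sigmoid(self.data), own=True)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * y, own=True)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data, own=True)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / y, own=True)
        return out

    def pow(self, exponent: float):
        out = _node(self.data**exponent, (self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1), own=True)
        return out

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy(), own=True)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))  # view: not owned
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = _node(y, (self,))

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot), own=True)

        out._backward = bwd
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Per-row normalization over the last axis with affine parameters."""
        mu = self.mean(axis=-1, keepdims=True)
        xc = self - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + eps).pow(-0.5)
        return xc * inv * gamma + beta


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype, copy=False)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def spmm(A: sp.spmatrix, X: Tensor) -> Tensor:
    """Sparse (constant) @ dense (differentiable) product."""
    X = _as_tensor(X)
    out = _node(A @ X.data, (X,))
    out._backward = lambda g: X._accumulate(A.T @ g, own=True)
    return out


def gather_rows(X: Tensor, idx: np.ndarray) -> Tensor:
    X = _as_tensor(X)
    out = _node(X.data[idx], (X,))

    def bwd(g):
        full = np.zeros_like(X.data)
        np.add.at(full, idx, g)
        X._accumulate(full, own=True)

    out._backward = bwd
    return out


def segment_sum(X: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Sum rows of X into n_seg buckets given per-row segment ids."""
    X = _as_tensor(X)
    shape = (n_seg,) + X.data.shape[1:]
    acc = np.zeros(shape, dtype=X.data.dtype)
    np.add.at(acc, seg, X.data)
    out = _node(acc, (X,))
    out._backward = lambda g: X._accumulate(g[seg], own=True)
    return out


def dropout(X: Tensor, p: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity when evaluating or p == 0."""
    if not train or p <= 0.0:
        return _as_tensor(X)
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(X.data.shape) >= p) / (1.0 - p)
    return _as_tensor(X) * Tensor(mask.astype(X.data.dtype))


# -- modules ---------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Tiny parameter container with recursive traversal."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = np.array(a, copy=True)


class Linear(Module):
    """Dense affine map with Glorot-uniform initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Parameter(rng.uniform(-limit, limit, (d_in, d_out)).astype(dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = _as_tensor(x) @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Parameter(np.ones(width, dtype=dtype))
        self.beta = Parameter(np.zeros(width, dtype=dtype))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return _as_tensor(x).layer_norm(self.gamma, self.beta, self.eps)


class AdamW(object):
    """AdamW with decoupled weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class EMA:
    """Exponential moving average of a parameter trajectory.

    shadow <- decay * shadow + (1 - decay) * current; decay 0 tracks the
    latest parameters exactly.
    """

    def __init__(self, params: Sequence[Parameter], decay: float):
        self.params = list(params)
        self.decay = decay
        self.shadow = [np.array(p.data, copy=True) for p in self.params]

    def update(self) -> None:
        d = self.decay
        for s, p in zip(self.shadow, self.params):
            s *= d
            s += (1 - d) * p.data

    def copy_to(self, params: Sequence[Parameter] | None = None) -> None:
        for s, p in zip(self.shadow, params or self.params):
            p.data = np.array(s, copy=True)

    def swap(self) -> list[np.ndarray]:
        """Swap shadow and live parameters; returns the stashed live copy."""
        live = [np.array(p.data, copy=True) for p in self.params]
        self.copy_to()
        return live
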