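"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The network in this package is small enough (well under a million parameters
at desk scale) that a hand-rolled tape suffices: every :class:`Tensor` records
its parents and a closure that accumulates gradients into them.  Only the
operations the network actually needs are implemented, and each op's backward
pass is checked against central finite differences in the test suite.

All arrays are float32 by default; gradients are accumulated in the same
dtype as the forward values.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

DEFAULT_DTYPE = np.float32

_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _as_array(x):
    """Scalars and non-float arrays become float32; float arrays keep their
    dtype, so float64 inputs run the whole tape in double precision."""
    a = np.asarray(x)
    if a.ndim == 0 or not np.issubdtype(a.dtype, np.floating):
        return a.astype(DEFAULT_DTYPE)
    return a


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None,
                 name: str | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self.name = name

    # -- structural helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag}, name={self.name})"

    # -- autograd engine ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)

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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if not node.requires_grad and node._parents:
                node.grad = None  # free intermediate grads eagerly

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            self._accumulate(_sum_to_shape(g, self.data.shape))
            other._accumulate(_sum_to_shape(g, other.data.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            self._accumulate(_sum_to_shape(g * other.data, self.data.shape))
            other._accumulate(_sum_to_shape(g * self.data, other.data.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            self._accumulate(_sum_to_shape(g / other.data, self.data.shape))
            other._accumulate(_sum_to_shape(-g * self.data / (other.data ** 2),
                                            other.data.shape))
        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions / shaping -----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


# ---------------------------------------------------------------------------
# free-function ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_sum_to_shape(ga, a.data.shape))
        b._accumulate(_sum_to_shape(gb, b.data.shape))
    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    out._backward = backward
    return out


def pad2d(x: Tensor, pad_h: tuple[int, int], pad_w: tuple[int, int]) -> Tensor:
    """Zero-pad the two spatial axes of a (..., H, W, C) tensor."""
    widths = [(0, 0)] * (x.ndim - 3) + [pad_h, pad_w, (0, 0)]
    out = Tensor(np.pad(x.data, widths), _parents=(x,))

    def backward(g):
        sl = tuple(slice(a, g.shape[i] - b) for i, (a, b) in enumerate(widths))
        x._accumulate(g[sl])
    out._backward = backward
    return out


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    """Take the top-left h×w spatial region of a (..., H, W, C) tensor."""
    sl = (Ellipsis, slice(0, h), slice(0, w), slice(None))
    out = Tensor(x.data[sl], _parents=(x,))

    def backward(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        x._accumulate(full)
    out._backward = backward
    return out


def roll2d(x: Tensor, shift_h: int, shift_w: int) -> Tensor:
    """Cyclic shift of the spatial axes of a (..., H, W, C) tensor."""
    axes = (x.ndim - 3, x.ndim - 2)
    out = Tensor(np.roll(x.data, (shift_h, shift_w), axis=axes), _parents=(x,))
    out._backward = lambda g: x._accumulate(np.roll(g, (-shift_h, -shift_w), axis=axes))
    return out


def take(table: Tensor, index: np.ndarray) -> Tensor:
    """Index the first axis of a parameter table (gather with scatter-add grad)."""
    out = Tensor(table.data[index], _parents=(table,))

    def backward(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, index, g)
        table._accumulate(acc)
    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Softmax with an optional additive (non-learnable) mask."""
    z = x.data if mask is None else x.data + mask
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _parents=(x,))

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))
    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    logp = z - lse
    out = Tensor(logp, _parents=(x,))

    def backward(g):
        p = np.exp(logp)
        x._accumulate(g - p * g.sum(axis=axis, keepdims=True))
    out._backward = backward
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd * _INV_SQRT2))
    out = Tensor(xd * cdf, _parents=(x,))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * xd * xd)
        x._accumulate(g * (cdf + xd * pdf).astype(xd.dtype))
    out._backward = backward
    return out


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def depthwise_conv2d(x: Tensor, w: Tensor) -> Tensor:
    """Per-channel 'same' cross-correlation of x:(B,H,W,C) with w:(K,K,C).

    Zero padding; each channel is filtered with its own K×K kernel.
    """
    k = w.data.shape[0]
    if w.data.shape[0] != w.data.shape[1]:
        raise ValueError("depthwise kernels must be square")
    p = k // 2
    B, H, W, C = x.data.shape
    if H < k or W < k:
        raise ValueError(f"spatial extent {H}x{W} smaller than kernel {k}x{k}")
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    # K² shifted multiply-adds: cheaper than materializing patch tensors
    y = np.zeros_like(x.data)
    for i in range(k):
        for j in range(k):
            y += w.data[i, j] * xp[:, i:i + H, j:j + W, :]
    out = Tensor(y, _parents=(x, w))

    def backward(g):
        gw = np.empty_like(w.data)
        for i in range(k):
            for j in range(k):
                gw[i, j] = np.einsum("bhwc,bhwc->c", xp[:, i:i + H, j:j + W, :], g,
                                     optimize=True)
        w._accumulate(gw)
        # dx: full correlation of g with the flipped kernel
        gp = np.pad(g, ((0, 0), (p, p), (p, p), (0, 0)))
        gx = np.zeros_like(x.data)
        wflip = w.data[::-1, ::-1, :]
        for i in range(k):
            for j in range(k):
                gx += wflip[i, j] * gp[:, i:i + H, j:j + W, :]
        x._accumulate(gx)
    out._backward = backward
    return out


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Deterministic bilinear resampling of a (B,H,W,C) tensor.

    Implemented as two fixed interpolation matrices (align_corners=False
    convention), so the operation is exactly linear and its transpose is the
    gradient.
    """
    B, H, W, C = x.data.shape
    R = _interp_matrix(H, out_h).astype(x.data.dtype)
    Cm = _interp_matrix(W, out_w).astype(x.data.dtype)
    y = np.einsum("ph,bhwc->bpwc", R, x.data, optimize=True)
    y = np.einsum("qw,bpwc->bpqc", Cm, y, optimize=True)
    out = Tensor(y, _parents=(x,))

    def backward(g):
        # transpose of the forward contractions
        gx = np.einsum("qw,bpqc->bpwc", Cm, g, optimize=True)
        gx = np.einsum("ph,bpwc->bhwc", R, gx, optimize=True)
        x._accumulate(gx.astype(x.data.dtype))
    out._backward = backward
    return out


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (n_out, n_in)."""
    M = np.zeros((n_out, n_in), dtype=np.float64)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        M[i, lo] += 1.0 - t
        M[i, hi] += t
    return M


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny module base: parameter discovery by attribute walking."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        params: dict[str, Parameter] = {}
        for key, value in vars(self).items():
            full = f"{prefix}{key}" if not prefix else f"{prefix}.{key}"
            if isinstance(value, Parameter):
                params[full] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(full))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{full}.{i}"))
                    elif isinstance(item, Parameter):
                        params[f"{full}.{i}"] = item
        return params

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> list[str]:
        """Copy arrays into parameters by name. With strict=False only
        shape-matching entries are copied; returns the names actually loaded."""
        own = self.named_parameters()
        loaded = []
        for k, v in state.items():
            if k not in own:
                if strict:
                    raise KeyError(f"unknown parameter {k}")
                continue
            if own[k].data.shape != v.shape:
                if strict:
                    raise ValueError(f"shape mismatch for {k}")
                continue
            own[k].data = v.astype(own[k].data.dtype).copy()
            loaded.append(k)
        if strict and set(own) - set(state):
            raise KeyError(f"missing parameters: {sorted(set(own) - set(state))}")
        return loaded


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal init (±2 std), the transformer default."""
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(DEFAULT_DTYPE)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int,
                 bias: bool = True, std: float = 0.02):
        self.weight = Parameter(trunc_normal(rng, (in_dim, out_dim), std))
        self.bias = Parameter(np.zeros(out_dim, dtype=DEFAULT_DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y
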