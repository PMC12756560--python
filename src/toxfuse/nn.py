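"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides the tensor/graph machinery the encoders and the fusion
network are built on: a :class:`Tensor` wrapping an ``ndarray`` with a backward
closure, the differentiable operations the architectures need (broadcasting
arithmetic, matmul, batched matmul, convolutions, pooling, gather/segment-sum),
a small :class:`Module` system with parameter traversal and state dicts, and an
Adam optimizer.  Everything runs on CPU in float32 by default and is fully
deterministic: all stochastic layers draw from an explicitly passed
``numpy.random.Generator``.

The engine is intentionally small — only what the model family here requires —
but each op's gradient is exact and checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32

# ---------------------------------------------------------------------------
# Tensor and autograd tape
# ---------------------------------------------------------------------------

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (evaluation paths)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=DTYPE)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (scalar unless grad given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _wrap(np.asarray(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _tracked(*ts: Tensor) -> bool:
    return _grad_enabled and any(t.requires_grad or t._parents or t._backward for t in ts)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(
        p.requires_grad or p._parents or p._backward is not None for p in parents
    ):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# Primitive ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    data = a.data**p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports 2-D and batched 3-D (equal batch dims)."""
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0.0))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def gelu(a: Tensor) -> Tensor:
    """GELU, tanh approximation (exact enough for these model scales)."""
    x = a.data
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    data = 0.5 * x * (1.0 + t)

    def backward(g):
        dinner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x**2)
        dt = (1.0 - t * t) * dinner
        a._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

    return _make(data, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    s = tsum(a, axis, keepdims)
    return mul(s, _wrap(np.asarray(1.0 / n, dtype=a.data.dtype)))


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes=None) -> Tensor:
    data = a.data.transpose(axes)

    def backward(g):
        if axes is None:
            a._accumulate(g.transpose())
        else:
            inv = np.argsort(axes)
            a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def take(a: Tensor, idx) -> Tensor:
    """Differentiable indexing (basic slices and integer arrays)."""
    data = a.data[idx]

    def backward(g):
        if a.grad is None:
            a.grad = np.zeros_like(a.data)
        if isinstance(idx, (np.ndarray, list)) or (
            isinstance(idx, tuple) and any(isinstance(i, (np.ndarray, list)) for i in idx)
        ):
            np.add.at(a.grad, idx, g)
        else:
            a.grad[idx] += g

    return _make(data.copy() if isinstance(data, np.ndarray) else data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    return _make(data, tuple(tensors), backward)


def segment_sum(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets (graph pooling, GINE
    neighbourhood aggregation).  ``segment_ids`` is a 1-D int array per row."""
    out = np.zeros((num_segments,) + a.data.shape[1:], dtype=a.data.dtype)
    np.add.at(out, segment_ids, a.data)

    def backward(g):
        a._accumulate(g[segment_ids])

    return _make(out, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = a.data.max(axis=axis, keepdims=True)  # detached shift
    e = exp(add(a, _wrap(-shift)))
    return mul(e, power(tsum(e, axis, keepdims=True), -1.0))


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably as max(x,0) + log1p(exp(-|x|))."""
    absx = add(relu(a), relu(-a))
    return add(relu(a), log(add(exp(-absx), _wrap(np.asarray(1.0, dtype=a.data.dtype)))))


# ---------------------------------------------------------------------------
# Convolution / pooling (stride-1 "same" convs + non-overlapping avg pools)
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2-D convolution, stride 1, zero ("same") padding for odd kernels.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,).
    """
    B, Cin, H, W = x.data.shape
    Cout, _, kh, kw = w.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (B, Cin, H, W, kh, kw) -> cols (B, H, W, Cin*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H, W, Cin * kh * kw)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out = cols @ wmat.T  # (B, H, W, Cout)
    if b is not None:
        out = out + b.data
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(g):
        gt = g.transpose(0, 2, 3, 1)  # (B, H, W, Cout)
        gw = np.tensordot(gt, cols, axes=([0, 1, 2], [0, 1, 2]))  # (Cout, Cin*kh*kw)
        w._accumulate(gw.reshape(w.data.shape))
        if b is not None:
            b._accumulate(gt.sum(axis=(0, 1, 2)))
        gcols = gt @ wmat  # (B, H, W, Cin*kh*kw)
        gcols = gcols.reshape(B, H, W, Cin, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + H, j : j + W] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        x._accumulate(gxp[:, :, ph : ph + H, pw : pw + W])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1-D convolution, stride 1, same padding. x: (B,Cin,L); w: (Cout,Cin,k)."""
    B, Cin, L = x.data.shape
    Cout, _, k = w.data.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,Cin,L,k)
    cols = win.transpose(0, 2, 1, 3).reshape(B, L, Cin * k)
    wmat = w.data.reshape(Cout, Cin * k)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(g):
        gt = g.transpose(0, 2, 1)  # (B, L, Cout)
        gw = np.tensordot(gt, cols, axes=([0, 1], [0, 1]))
        w._accumulate(gw.reshape(w.data.shape))
        if b is not None:
            b._accumulate(gt.sum(axis=(0, 1)))
        gcols = (gt @ wmat).reshape(B, L, Cin, k)
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[:, :, j : j + L] += gcols[:, :, :, j].transpose(0, 2, 1)
        x._accumulate(gxp[:, :, p : p + L])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k×k average pooling; spatial dims must divide by k."""
    B, C, H, W = x.data.shape
    data = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accumulate(gx)

    return _make(data, (x,), backward)


def avg_pool1d(x: Tensor, k: int) -> Tensor:
    B, C, L = x.data.shape
    data = x.data.reshape(B, C, L // k, k).mean(axis=3)

    def backward(g):
        x._accumulate(np.repeat(g, k, axis=2) / k)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter traversal, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Tensor]]:
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        seen, out = set(), []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out: OrderedDict[str, np.ndarray] = OrderedDict()
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, buf in self._named_buffers():
            out[name] = buf.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=params[name].data.dtype).reshape(
                    params[name].data.shape
                )
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown parameter {name!r}")

    def _named_buffers(self, prefix: str = "") -> Iterable[tuple[str, np.ndarray]]:
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v._named_buffers(prefix=full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_buffers(prefix=f"{full}.{i}.")
            elif name.startswith("buf_") and isinstance(v, np.ndarray):
                yield full, v


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, in_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = add(out, self.bias)
        return out


class Embedding(Module):
    def __init__(self, n_embed: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_embed, dim)).astype(DTYPE))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return take(self.weight, np.asarray(ids, dtype=np.int64))


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        assert 0.0 <= p < 1.0
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0 or rng is None:
            return x
        keep = (rng.random(x.data.shape) >= self.p).astype(x.data.dtype)
        return mul(x, _wrap(keep / (1.0 - self.p)))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=-1, keepdims=True)
        xc = add(x, -mu)
        var = tmean(mul(xc, xc), axis=-1, keepdims=True)
        inv = power(add(var, _wrap(np.asarray(self.eps, dtype=DTYPE))), -0.5)
        return add(mul(mul(xc, inv), self.gamma), self.beta)


class BatchNorm(Module):
    """Batch normalization over the given reduction axes (channel dim kept).

    ``axes=(0,)`` for (B, C) inputs, ``(0, 2, 3)`` for (B, C, H, W),
    ``(0, 2)`` for (B, C, L).
    """

    def __init__(self, num_features: int, axes: tuple[int, ...] = (0,), eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.axes = axes
        self.eps = eps
        self.momentum = momentum
        self.buf_running_mean = np.zeros(num_features, dtype=DTYPE)
        self.buf_running_var = np.ones(num_features, dtype=DTYPE)

    def _bshape(self, ndim: int):
        shape = [1] * ndim
        chan_axis = next(i for i in range(ndim) if i not in self.axes)
        shape[chan_axis] = -1
        return shape

    def __call__(self, x: Tensor) -> Tensor:
        shape = self._bshape(x.data.ndim)
        # frozen gamma/beta => the layer acts as a fixed feature extractor:
        # running statistics are used and no longer updated
        if self.training and self.gamma.requires_grad:
            mu = tmean(x, axis=self.axes, keepdims=True)
            xc = add(x, -mu)
            var = tmean(mul(xc, xc), axis=self.axes, keepdims=True)
            m = self.momentum
            self.buf_running_mean[...] = (1 - m) * self.buf_running_mean + m * mu.data.reshape(-1)
            self.buf_running_var[...] = (1 - m) * self.buf_running_var + m * var.data.reshape(-1)
        else:
            mu = _wrap(self.buf_running_mean.reshape(shape))
            xc = add(x, -mu)
            var = _wrap(self.buf_running_var.reshape(shape))
        inv = power(add(var, _wrap(np.asarray(self.eps, dtype=DTYPE))), -0.5)
        return add(
            mul(mul(xc, inv), reshape(self.gamma, shape)),
            reshape(self.beta, shape),
        )


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, cin * k * k, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, cin * k, (cout, cin, k)))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention over (B, T, D) token matrices.

    Returns the attended tokens and the per-head row-stochastic attention maps
    (B, heads, T, T).  An optional key mask (B, T) with 1 = real token restricts
    attention to unmasked positions.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.dh = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None):
        B, T, D = x.data.shape
        H, dh = self.n_heads, self.dh

        def split(t: Tensor) -> Tensor:
            return transpose(reshape(t, (B, T, H, dh)), (0, 2, 1, 3)).reshape((B * H, T, dh))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = mul(matmul(q, transpose(k, (0, 2, 1))),
                     _wrap(np.asarray(1.0 / math.sqrt(dh), dtype=DTYPE)))
        if key_mask is not None:
            bias_mask = np.where(key_mask[:, None, None, :] > 0, 0.0, -1e9).astype(DTYPE)
            bias_mask = np.broadcast_to(bias_mask, (B, H, T, T)).reshape(B * H, T, T)
            scores = add(scores, _wrap(bias_mask))
        attn = softmax(scores, axis=-1)  # (B*H, T, T)
        ctx = matmul(attn, v)  # (B*H, T, dh)
        ctx = reshape(transpose(reshape(ctx, (B, H, T, dh)), (0, 2, 1, 3)), (B, T, D))
        out = self.wo(ctx)
        return out, attn.data.reshape(B, H, T, T)


class Adam:
    """Adam optimizer over an explicit parameter list (trainable only)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sinusoidal_position_encoding(length: int, dim: int) -> np.ndarray:
    """Classic fixed sin/cos positional encoding table (length, dim)."""
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, 2 * i / dim)
    pe = np.zeros((length, dim), dtype=DTYPE)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe
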