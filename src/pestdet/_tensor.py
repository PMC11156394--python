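"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
recorded graph.  Only the primitives needed by the detector are implemented
(broadcast arithmetic, batched matmul, reshape/transpose, fancy-index gather,
padding, reductions, exp/log/tanh, softmax, 2x nearest upsampling).  Larger
building blocks (convolution, attention, pooling) are composed from these in
:mod:`pestdet.nn` and the model modules.

Gradients are accumulated in float32.  A global no-grad switch
(:func:`no_grad`) disables graph recording for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
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
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients/graph to bound memory
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- primitives ------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** np.float32(exponent)

    def backward(g):
        if a.requires_grad:
            a._accum(g * np.float32(exponent) * a.data ** np.float32(exponent - 1.0))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (a.data > 0.0))

    return _make(data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)
    in_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(in_shape))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def take(a, idx) -> Tensor:
    """Indexing / gather; supports basic slices and integer-array indices."""
    a = _as_tensor(a)
    data = a.data[idx]
    in_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            full = np.zeros(in_shape, dtype=np.float32)
            np.add.at(full, idx, g)
            a._accum(full)

    return _make(data, (a,), backward)


def pad2d(a, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the two leading spatial axes of an (H, W, ...) tensor."""
    a = _as_tensor(a)
    widths = [(pad_h, pad_h), (pad_w, pad_w)] + [(0, 0)] * (a.ndim - 2)
    data = np.pad(a.data, widths)

    def backward(g):
        if a.requires_grad:
            sl = (slice(pad_h, g.shape[0] - pad_h), slice(pad_w, g.shape[1] - pad_w))
            a._accum(g[sl])

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accum(np.broadcast_to(g, in_shape).astype(np.float32))
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(ax % len(in_shape) for ax in axes)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                a._accum(np.broadcast_to(g, in_shape).astype(np.float32))

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis, keepdims), 1.0 / n)


def tmax(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                mask = (a.data == data).astype(np.float32)
                a._accum(mask * g / mask.sum())
                return
            expanded = a.data.max(axis=axis, keepdims=True)
            mask = (a.data == expanded)
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            gk = g if keepdims else np.expand_dims(g, axes)
            # split gradient among ties to keep the op well-defined
            counts = mask.sum(axis=axis, keepdims=True)
            a._accum(mask * gk / counts)

    return _make(data, (a,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(data, tensors, backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax; -inf entries yield exactly zero weight."""
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accum(data * (g - dot))

    return _make(data, (a,), backward)


def upsample2x(a) -> Tensor:
    """Nearest-neighbour 2x upsampling of an (H, W, C) tensor."""
    a = _as_tensor(a)
    data = np.repeat(np.repeat(a.data, 2, axis=0), 2, axis=1)
    H, W = a.data.shape[:2]

    def backward(g):
        if a.requires_grad:
            gr = g.reshape(H, 2, W, 2, *g.shape[2:]).sum(axis=(1, 3))
            a._accum(gr)

    return _make(data, (a,), backward)


def gelu(a) -> Tensor:
    """GELU activation (tanh approximation)."""
    a = _as_tensor(a)
    c = np.sqrt(2.0 / np.pi).astype(np.float32)
    inner = mul(add(a, mul(power(a, 3.0), 0.044715)), c)
    return mul(mul(a, add(tanh(inner), 1.0)), 0.5)
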