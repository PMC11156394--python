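"""Neural-network layers and optimisation on top of :mod:`pestdet._tensor`.

Layers operate on single images in channels-last layout: spatial tensors are
(H, W, C) and token grids are (H, W, C).  Batching is realised by gradient
accumulation in the training loop, which keeps the layer code simple and
matches the effective-batch semantics of the training schedule.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import _tensor as T
from ._tensor import Tensor


def trunc_normal(shape, std: float, rng: np.random.Generator) -> np.ndarray:
    """Truncated normal init (|x| <= 2 std), the conventional transformer init."""
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2.0 * std, 2.0 * std).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: parameter discovery, train/eval flag, state dict."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _walk(value, name):
        """Yield (name, leaf) pairs from arbitrarily nested lists/tuples."""
        if isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._walk(item, f"{name}.{i}")
        else:
            yield name, value

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            for _, leaf in self._walk(v, ""):
                if isinstance(leaf, Module):
                    yield from leaf.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            for name, leaf in self._walk(v, f"{prefix}{k}"):
                if isinstance(leaf, Parameter):
                    yield name, leaf
                elif isinstance(leaf, Module):
                    yield from leaf.named_parameters(f"{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features), dtype=np.float32)
        else:
            w = trunc_normal((in_features, out_features), 0.02, rng)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = T.power(var + self.eps, -0.5)
        return xc * inv * self.gamma + self.beta


class Mlp(Module):
    """Two-layer feed-forward block with GELU, hidden = ratio * dim."""

    def __init__(self, dim: int, rng: np.random.Generator, ratio: float = 4.0):
        super().__init__()
        hidden = int(dim * ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(T.gelu(self.fc1(x)))


class Conv2d(Module):
    """2-D convolution on (H, W, Cin) tensors via gather + matmul.

    Stride 1, 'same' zero padding for odd kernels; the index map is cached
    per input shape.  1x1 convolutions bypass the gather entirely.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        self.kernel = kernel
        self.in_ch = in_ch
        fan_in = kernel * kernel * in_ch
        if zero_init:
            w = np.zeros((fan_in, out_ch), dtype=np.float32)
        else:
            # He-style init, appropriate for the ReLU towers in heads
            w = (rng.standard_normal((fan_in, out_ch))
                 * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self._idx_cache: dict[tuple[int, int], tuple] = {}

    def _indices(self, H: int, W: int):
        key = (H, W)
        if key not in self._idx_cache:
            k = self.kernel
            ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            di, dj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
            rows = ii[:, :, None, None] + di[None, None]
            cols = jj[:, :, None, None] + dj[None, None]
            self._idx_cache[key] = (rows, cols)
        return self._idx_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        H, W, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k = self.kernel
        if k == 1:
            return x @ self.weight.reshape(C, -1) + self.bias
        pad = k // 2
        xp = T.pad2d(x, pad, pad)
        rows, cols = self._indices(H, W)
        patches = xp[rows, cols]                       # (H, W, k, k, C)
        flat = patches.reshape((H, W, k * k * C))
        return flat @ self.weight + self.bias


def max_pool_2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling of an (H, W, C) tensor (H, W even)."""
    H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool_2x2 needs even dims, got {H}x{W}")
    r = x.reshape((H // 2, 2, W // 2, 2, C))
    return r.max(axis=3).max(axis=1)


class SGD:
    """SGD with classical momentum and (coupled) L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
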