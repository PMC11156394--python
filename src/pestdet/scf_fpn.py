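"""SCF-FPN neck: per-level sliding-window contextual-feature self-attention
followed by top-down pyramid fusion.

For each backbone level the SCF module
(1) reduces channels to the neck width C with a 1x1 convolution (X),
(2) unfolds every U x V neighbourhood around each position into a regional
    tensor R[i,j,u,v,:] = X[i+u-U//2, j+v-V//2, :] with zero padding,
(3) forms the autocorrelation tensor D = R ⊙ X' (X broadcast over the
    window axes), flattened row-major over (u, v) with channels fastest to
    C' = U*V*C channels — each entry is the product of a centre feature
    with the same channel of a neighbour, a window-local self-similarity
    map,
(4) concatenates G = [X; D] (C + C' channels) and remaps it with two 1x1
    convolutions back to C channels, added residually: A = X + I'.

A 3x3 convolution then smooths each enhanced level, and a standard
top-down pathway (nearest 2x upsampling + lateral sum + 3x3 smoothing)
produces P3/P4/P5, with P6 a stride-2 max pool of P5.  Window sizes default
to (7,7)/(5,5)/(3,3) for the stride-8/16/32 levels: finer levels see more
context, coarser levels stay local.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from . import nn
from .backbone import FeatureMap


@dataclass(frozen=True)
class SCFConfig:
    """Neck width and per-level (U, V) neighbourhood windows."""

    neck_channels: int = 256
    windows: tuple[tuple[int, int], ...] = ((7, 7), (5, 5), (3, 3))

    def __post_init__(self):
        if self.neck_channels < 1:
            raise ValueError("neck_channels must be >= 1")
        for u, v in self.windows:
            if u < 1 or v < 1 or u % 2 == 0 or v % 2 == 0:
                raise ValueError(f"window sides must be odd and >= 1, got "
                                 f"({u}, {v})")

    @classmethod
    def uniform(cls, side: int, neck_channels: int = 256) -> "SCFConfig":
        """All levels share one window — the ablation axis (3/5/7 uniform
        versus the mixed default)."""
        return cls(neck_channels=neck_channels,
                   windows=((side, side),) * 3)


def neighborhood_unfold(x: Tensor | np.ndarray, U: int, V: int) -> Tensor:
    """Regional tensor R: R[i,j,u,v,:] = X[i+u-U//2, j+v-V//2, :].

    Zero padding outside the grid keeps the output aligned with X
    (shape H x W x U x V x C).
    """
    if U % 2 == 0 or V % 2 == 0:
        raise ValueError(f"window sides must be odd, got ({U}, {V})")
    if not isinstance(x, Tensor):
        x = Tensor(x)
    H, W, C = x.shape
    xp = T.pad2d(x, U // 2, V // 2)
    ii = np.arange(H)[:, None, None, None] + np.arange(U)[None, None, :, None]
    jj = np.arange(W)[None, :, None, None] + np.arange(V)[None, None, None, :]
    ii = np.broadcast_to(ii, (H, W, U, V))
    jj = np.broadcast_to(jj, (H, W, U, V))
    return xp[ii, jj]


def autocorrelation(R: Tensor, x: Tensor) -> Tensor:
    """Window autocorrelation D = R ⊙ X', flattened to H x W x (U*V*C).

    X' is X broadcast along the window axes; the (u, v, c) flattening is
    row-major with channels fastest, so
    D[i, j, (u*V + v)*C + c] = X[i+du, j+dv, c] * X[i, j, c].
    """
    H, W, U, V, C = R.shape
    x_prime = x.reshape(H, W, 1, 1, C)
    D = R * x_prime
    return D.reshape(H, W, U * V * C)


class EmbedFuse(nn.Module):
    """Fuse X with its autocorrelation D and re-embed residually.

    G = [X; D] (channel concat, X first), I = conv1x1(G) -> C,
    I' = conv1x1(I) -> C, A = X + I'.  Both projections are
    zero-initialised so a fresh module is an exact identity (A == X) and
    the attention branch cannot hurt training at initialisation.
    """

    def __init__(self, channels: int, U: int, V: int,
                 rng: np.random.Generator):
        super().__init__()
        c_prime = U * V * channels
        self.proj1 = nn.Conv2d(channels + c_prime, channels, 1, rng,
                               zero_init=True)
        self.proj2 = nn.Conv2d(channels, channels, 1, rng, zero_init=True)

    def forward(self, x: Tensor, D: Tensor) -> Tensor:
        G = T.concatenate([x, D], axis=-1)
        I = self.proj1(G)
        I_prime = self.proj2(I)
        return x + I_prime


class SCFModule(nn.Module):
    """One level's enhancement: reduce -> unfold -> autocorrelate -> fuse."""

    def __init__(self, in_channels: int, neck_channels: int,
                 window: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.window = window
        self.reduce = nn.Conv2d(in_channels, neck_channels, 1, rng)
        self.fuse = EmbedFuse(neck_channels, *window, rng)

    def forward(self, feat: Tensor) -> Tensor:
        U, V = self.window
        x = self.reduce(feat)
        R = neighborhood_unfold(x, U, V)
        D = autocorrelation(R, x)
        return self.fuse(x, D)


def reduce_channels(feat: FeatureMap, module: nn.Conv2d) -> Tensor:
    """1x1 projection of a backbone level to the neck width."""
    return module(feat.data)


class SCFNeck(nn.Module):
    """Full neck: per-level SCF + 3x3 conv, then the top-down pyramid.

    P5 = A3; P4 = A2 + up2(P5); P3 = A1 + up2(P4); each P level gets one
    3x3 smoothing conv; P6 = 2x2 stride-2 max pool of P5.
    """

    def __init__(self, in_channels: tuple[int, int, int],
                 config: SCFConfig = SCFConfig(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        C = config.neck_channels
        self.scf = [SCFModule(ic, C, w, rng)
                    for ic, w in zip(in_channels, config.windows)]
        self.level_conv = [nn.Conv2d(C, C, 3, rng) for _ in range(3)]
        self.smooth = [nn.Conv2d(C, C, 3, rng) for _ in range(3)]

    def enhance(self, feat: FeatureMap, level: int) -> FeatureMap:
        """SCF enhancement + 3x3 conv for one level (1-based, feat1..feat3)."""
        if level not in (1, 2, 3):
            raise ValueError(f"level must be 1, 2 or 3, got {level}")
        A = self.scf[level - 1](feat.data)
        return FeatureMap(self.level_conv[level - 1](A), stride=feat.stride)

    def build_pyramid(self, A1: FeatureMap, A2: FeatureMap, A3: FeatureMap
                      ) -> tuple[FeatureMap, ...]:
        if (A1.stride, A2.stride, A3.stride) != (8, 16, 32):
            raise ValueError("expected strides 8/16/32 for A1/A2/A3")
        p5 = A3.data
        p4 = A2.data + T.upsample2x(p5)
        p3 = A1.data + T.upsample2x(p4)
        p3 = self.smooth[0](p3)
        p4 = self.smooth[1](p4)
        p5 = self.smooth[2](p5)
        p6 = nn.max_pool_2x2(p5)
        return (FeatureMap(p3, 8), FeatureMap(p4, 16),
                FeatureMap(p5, 32), FeatureMap(p6, 64))

    def forward(self, feats: tuple[FeatureMap, FeatureMap, FeatureMap]
                ) -> tuple[FeatureMap, ...]:
        A = [self.enhance(f, lvl) for lvl, f in enumerate(feats, start=1)]
        return self.build_pyramid(*A)


def scf_enhance(feat: FeatureMap, neck: SCFNeck, level: int) -> FeatureMap:
    """Functional wrapper over :meth:`SCFNeck.enhance`."""
    return neck.enhance(feat, level)


def build_pyramid(neck: SCFNeck, A1: FeatureMap, A2: FeatureMap,
                  A3: FeatureMap) -> tuple[FeatureMap, ...]:
    """Functional wrapper over :meth:`SCFNeck.build_pyramid`."""
    return neck.build_pyramid(A1, A2, A3)


# -- independent reference implementations (test oracles) ------------------


def unfold_reference(x: np.ndarray, U: int, V: int) -> np.ndarray:
    """Five-nested-loop reference for :func:`neighborhood_unfold`."""
    H, W, C = x.shape
    out = np.zeros((H, W, U, V, C), dtype=x.dtype)
    for i in range(H):
        for j in range(W):
            for u in range(U):
                for v in range(V):
                    ii = i + u - U // 2
                    jj = j + v - V // 2
                    if 0 <= ii < H and 0 <= jj < W:
                        out[i, j, u, v] = x[ii, jj]
    return out


def autocorrelation_reference(x: np.ndarray, U: int, V: int) -> np.ndarray:
    """Loop reference for the flattened autocorrelation tensor."""
    H, W, C = x.shape
    R = unfold_reference(x, U, V)
    out = np.zeros((H, W, U * V * C), dtype=x.dtype)
    for i in range(H):
        for j in range(W):
            for u in range(U):
                for v in range(V):
                    for c in range(C):
                        out[i, j, (u * V + v) * C + c] = (
                            R[i, j, u, v, c] * x[i, j, c])
    return out
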