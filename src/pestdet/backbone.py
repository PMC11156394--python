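"""Hierarchical shifted-window attention backbone.

An input image is cut into non-overlapping 4x4 patches (48 raw channels),
linearly embedded, and processed by four stages of window-attention blocks;
stages 2-4 each start with a patch-merging downsample (2x2 concat + linear,
halving resolution and doubling channels).  Self-attention is computed
inside M x M token windows; alternate blocks cyclically shift the grid by
M/2 so attention crosses window borders, with a mask that keeps tokens from
non-adjacent pre-shift regions at exactly zero attention weight.  Each block
applies the pre-norm residual pair

    z_hat = Attn(LN(z_in)) + z_in
    z_out = MLP(LN(z_hat)) + z_hat

where Attn is plain window attention or its shifted variant.  The backbone
returns the outputs of stages 2, 3 and 4 (strides 8/16/32, channels
2C/4C/8C) — the multi-scale features the neck consumes; with the default
embedding width C=128 and a 1280 px input these are (160,160,256),
(80,80,512) and (40,40,1024), matching small, medium and large targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from . import nn


@dataclass
class FeatureMap:
    """Dense H x W x C activation grid with its stride w.r.t. the input."""

    data: Tensor
    stride: int

    def __post_init__(self):
        if self.stride not in (4, 8, 16, 32, 64):
            raise ValueError(f"unsupported stride {self.stride}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def channels(self) -> int:
        return self.data.shape[-1]


@dataclass(frozen=True)
class BackboneConfig:
    embed_dim: int = 128
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (4, 8, 16, 32)
    attn_window: int = 8
    mlp_ratio: float = 4.0

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.num_heads) != 4:
            raise ValueError("depths and num_heads must have 4 stages")
        for d in self.depths:
            if d % 2:
                raise ValueError("stage depths must be even "
                                 "(plain/shifted blocks alternate in pairs)")

    @classmethod
    def tiny(cls) -> "BackboneConfig":
        """Small CPU profile: same topology, reduced width/depth/window."""
        return cls(embed_dim=32, depths=(2, 2, 2, 2), num_heads=(2, 4, 8, 8),
                   attn_window=4, mlp_ratio=2.0)

    def validate_input(self, h: int, w: int) -> None:
        div = 4 * self.attn_window * 8
        for name, v in (("height", h), ("width", w)):
            if v % div:
                raise ValueError(
                    f"input {name} {v} not divisible by 4*M*8 = {div} "
                    f"(window M={self.attn_window} must tile every stage)")


# -- token-grid bookkeeping ------------------------------------------------


def patch_partition(image):
    """(H, W, 3) raster -> (H/4, W/4, 48) token grid.

    Each token is the flattening of one 4x4x3 block, row-major within the
    patch with channels fastest; the map is lossless.  Works on ndarrays
    and Tensors alike.
    """
    H, W, C = image.shape
    if H % 4 or W % 4:
        raise ValueError(f"image dims {H}x{W} not divisible by 4")
    r = image.reshape(H // 4, 4, W // 4, 4, C)
    return r.transpose(0, 2, 1, 3, 4).reshape(H // 4, W // 4, 16 * C)


def patch_unpartition(tokens, patch: int = 4, channels: int = 3):
    """Exact inverse of :func:`patch_partition`."""
    Hp, Wp, _ = tokens.shape
    r = tokens.reshape(Hp, Wp, patch, patch, channels)
    return r.transpose(0, 2, 1, 3, 4).reshape(Hp * patch, Wp * patch, channels)


def window_partition(x, M: int):
    """(H, W, C) grid -> (num_windows, M, M, C) stack of M x M windows."""
    H, W, C = x.shape
    if H % M or W % M:
        raise ValueError(f"grid {H}x{W} not divisible by window {M}")
    r = x.reshape(H // M, M, W // M, M, C)
    return r.transpose(0, 2, 1, 3, 4).reshape((H // M) * (W // M), M, M, C)


def window_reverse(windows, M: int, H: int, W: int):
    """Exact inverse of :func:`window_partition`."""
    C = windows.shape[-1]
    r = windows.reshape(H // M, W // M, M, M, C)
    return r.transpose(0, 2, 1, 3, 4).reshape(H, W, C)


def shift_zone_labels(H: int, W: int, M: int, shift: int) -> np.ndarray:
    """Label each token of the cyclically shifted grid by its pre-shift zone.

    With 0 < shift < M and a grid larger than one window the labels take 9
    distinct values (3 row bands x 3 col bands): the spatial zones whose
    tokens may not attend across after the shift.
    """
    labels = np.zeros((H, W), dtype=np.int64)
    h_bands = (slice(0, H - M), slice(H - M, H - shift), slice(H - shift, H))
    w_bands = (slice(0, W - M), slice(W - M, W - shift), slice(W - shift, W))
    z = 0
    for hs in h_bands:
        for ws in w_bands:
            labels[hs, ws] = z
            z += 1
    return labels


def shifted_attention_mask(H: int, W: int, M: int, shift: int) -> np.ndarray:
    """(num_windows, M*M, M*M) additive mask: 0 within a zone pair that may
    interact, -inf across pre-shift zone boundaries."""
    labels = shift_zone_labels(H, W, M, shift)
    labels = np.roll(labels, (-shift, -shift), axis=(0, 1))
    win = window_partition(labels[:, :, None].astype(np.float64), M)
    win = win.reshape(-1, M * M)
    diff = win[:, :, None] - win[:, None, :]
    mask = np.where(diff == 0, 0.0, -np.inf).astype(np.float32)
    return mask


# -- modules ---------------------------------------------------------------


class LinearEmbed(nn.Module):
    """Per-token affine map from raw 48-channel patches to the model width."""

    def __init__(self, in_ch: int, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(in_ch, embed_dim, rng)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, tokens: Tensor) -> Tensor:
        return self.norm(self.proj(tokens))


class WindowAttention(nn.Module):
    """Multi-head self-attention inside M x M windows with relative
    position bias.  Set ``store_attn`` to keep the last attention
    probabilities (num_windows, heads, N, N) for inspection."""

    def __init__(self, dim: int, num_heads: int, M: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by heads {num_heads}")
        self.dim = dim
        self.num_heads = num_heads
        self.M = M
        self.scale = (dim // num_heads) ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.rel_bias = nn.Parameter(
            nn.trunc_normal(((2 * M - 1) ** 2, num_heads), 0.02, rng))
        self._rel_index = self._relative_index(M)
        self.store_attn = False
        self.last_attn: np.ndarray | None = None

    @staticmethod
    def _relative_index(M: int) -> np.ndarray:
        coords = np.stack(np.meshgrid(np.arange(M), np.arange(M),
                                      indexing="ij")).reshape(2, -1)
        rel = coords[:, :, None] - coords[:, None, :]   # (2, N, N)
        rel = rel + (M - 1)
        return rel[0] * (2 * M - 1) + rel[1]            # (N, N)

    def forward(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        nW, N, C = windows.shape
        h, d = self.num_heads, self.dim // self.num_heads
        qkv = self.qkv(windows)                          # (nW, N, 3C)
        q = qkv[:, :, :C].reshape(nW, N, h, d).transpose(0, 2, 1, 3)
        k = qkv[:, :, C:2 * C].reshape(nW, N, h, d).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * C:].reshape(nW, N, h, d).transpose(0, 2, 1, 3)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale  # (nW, h, N, N)
        bias = self.rel_bias[self._rel_index].transpose(2, 0, 1)  # (h, N, N)
        attn = attn + bias
        if mask is not None:
            attn = attn + Tensor(mask[:, None, :, :])
        probs = T.softmax(attn, axis=-1)
        if self.store_attn:
            self.last_attn = probs.data.copy()
        out = (probs @ v).transpose(0, 2, 1, 3).reshape(nW, N, C)
        return self.proj(out)


class SwinBlock(nn.Module):
    """One pre-norm attention + MLP block, plain or shifted."""

    def __init__(self, dim: int, num_heads: int, M: int, shifted: bool,
                 rng: np.random.Generator, mlp_ratio: float = 4.0):
        super().__init__()
        self.M = M
        self.shifted = shifted
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, M, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, rng, ratio=mlp_ratio)
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def _attend(self, x: Tensor) -> Tensor:
        H, W, C = x.shape
        M = self.M
        # shifting a grid that is a single window would be a no-op bijection
        shift = M // 2 if (self.shifted and (H > M or W > M)) else 0
        if shift:
            rows = (np.arange(H) + shift) % H
            cols = (np.arange(W) + shift) % W
            x = x[rows][:, cols]
            key = (H, W)
            if key not in self._mask_cache:
                self._mask_cache[key] = shifted_attention_mask(H, W, M, shift)
            mask = self._mask_cache[key]
        else:
            mask = None
        win = window_partition(x, M).reshape(-1, M * M, C)
        out = self.attn(win, mask)
        out = window_reverse(out.reshape(-1, M, M, C), M, H, W)
        if shift:
            rows = (np.arange(H) - shift) % H
            cols = (np.arange(W) - shift) % W
            out = out[rows][:, cols]
        return out

    def forward(self, x: Tensor) -> Tensor:
        z_hat = self._attend(self.norm1(x)) + x
        return self.mlp(self.norm2(z_hat)) + z_hat


class PatchMerge(nn.Module):
    """2x2 neighbourhood concat (4C, row-major order) + linear to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.reduction = nn.Linear(4 * dim, 2 * dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"patch_merge needs even dims, got {H}x{W}")
        r = x.reshape(H // 2, 2, W // 2, 2, C)
        merged = r.transpose(0, 2, 1, 3, 4).reshape(H // 2, W // 2, 4 * C)
        return self.reduction(merged)


def patch_merge(x: FeatureMap, module: PatchMerge) -> FeatureMap:
    """FeatureMap wrapper: halve H, W; double C and stride."""
    return FeatureMap(module(x.data), stride=x.stride * 2)


_NORM_MEAN = 0.5
_NORM_STD = 0.25


class SwinBackbone(nn.Module):
    """Four-stage backbone producing (feat1, feat2, feat3)."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        C = config.embed_dim
        self.embed = LinearEmbed(48, C, rng)
        self.stages: list[list[nn.Module]] = []
        self.merges: list[PatchMerge] = []
        dims = [C, 2 * C, 4 * C, 8 * C]
        for s in range(4):
            if s > 0:
                self.merges.append(PatchMerge(dims[s - 1], rng))
            blocks = [SwinBlock(dims[s], config.num_heads[s],
                                config.attn_window, shifted=(b % 2 == 1),
                                rng=rng, mlp_ratio=config.mlp_ratio)
                      for b in range(config.depths[s])]
            self.stages.append(blocks)

    def forward(self, image: np.ndarray | Tensor
                ) -> tuple[FeatureMap, FeatureMap, FeatureMap]:
        if isinstance(image, Tensor):
            x = image
        else:
            arr = np.asarray(image, dtype=np.float32)
            if arr.max() > 1.5:  # uint8-range raster
                arr = arr / 255.0
            x = Tensor((arr - _NORM_MEAN) / _NORM_STD)
        H, W, _ = x.shape
        self.config.validate_input(H, W)
        tokens = patch_partition(x)
        z = self.embed(tokens)
        feats = []
        for s in range(4):
            if s > 0:
                z = self.merges[s - 1](z)
            for block in self.stages[s]:
                z = block(z)
            if s >= 1:
                feats.append(FeatureMap(z, stride=4 * 2 ** s))
        return tuple(feats)


def forward_backbone(image, backbone: SwinBackbone):
    """feat1/feat2/feat3 at strides 8/16/32 with channels 2C/4C/8C."""
    return backbone(image)
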