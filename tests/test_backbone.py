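"""Backbone contracts: partition bijections, residual identities, masking."""

import numpy as np
import pytest

from pestdet import _tensor as T
from pestdet._tensor import Tensor
from pestdet.backbone import (BackboneConfig, LinearEmbed, PatchMerge,
                              SwinBackbone, SwinBlock, WindowAttention,
                              patch_partition, patch_unpartition,
                              shift_zone_labels, shifted_attention_mask,
                              window_partition, window_reverse)


def test_patch_partition_shapes_and_constant_value():
    out = patch_partition(np.full((8, 8, 3), 2.5, dtype=np.float32))
    assert out.shape == (2, 2, 48)
    assert np.all(out == 2.5)
    big = patch_partition(np.zeros((1280, 1280, 3), dtype=np.float32))
    assert big.shape == (320, 320, 48)


def test_patch_partition_is_bijective():
    rng = np.random.default_rng(0)
    img = rng.standard_normal((16, 24, 3)).astype(np.float32)
    assert np.array_equal(patch_unpartition(patch_partition(img)), img)


def test_patch_partition_rejects_nondivisible():
    with pytest.raises(ValueError, match="divisible"):
        patch_partition(np.zeros((10, 8, 3)))


def test_linear_embed_affine_contract():
    rng = np.random.default_rng(0)
    emb = LinearEmbed(48, 128, rng)
    tokens = Tensor(rng.standard_normal((4, 4, 48)).astype(np.float32))
    out = emb(tokens)
    assert out.shape == (4, 4, 128)
    # zero weight + zero bias -> zero output (before the norm's beta shift)
    emb.proj.weight.data[:] = 0
    emb.proj.bias.data[:] = 0
    raw = emb.proj(tokens)
    assert np.all(raw.data == 0)


def test_window_partition_counts_and_roundtrip():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((8, 8, 6)).astype(np.float32)
    win = window_partition(x, 4)
    assert win.shape[0] == 4  # 8x8 grid, window 4 -> 4 windows
    assert np.array_equal(window_reverse(win, 4, 8, 8), x)
    with pytest.raises(ValueError):
        window_partition(x, 3)


def test_shift_creates_nine_zones_from_four_windows():
    """Cyclic shift turns the 4-window tiling into 9 attention zones."""
    labels = shift_zone_labels(8, 8, 4, 2)
    assert len(np.unique(labels)) == 9
    mask = shifted_attention_mask(8, 8, 4, 2)
    assert mask.shape == (4, 16, 16)
    # masked entries are -inf, allowed entries exactly 0
    assert set(np.unique(mask[np.isfinite(mask)])) == {0.0}
    assert np.isneginf(mask).any()


def test_swin_block_zero_weights_is_identity():
    """Both residual branches vanish when all projections are zeroed."""
    rng = np.random.default_rng(0)
    block = SwinBlock(16, 2, 4, shifted=False, rng=rng)
    for _, p in block.named_parameters():
        if p.data.ndim >= 1:
            p.data[:] = 0
    block.norm1.gamma.data[:] = 1  # norms stay at identity scaling
    block.norm2.gamma.data[:] = 1
    x = Tensor(rng.standard_normal((8, 8, 16)).astype(np.float32))
    out = block(x)
    assert np.array_equal(out.data, x.data)


def test_swin_block_preserves_shape_and_shift_equivalence_on_constant():
    rng = np.random.default_rng(3)
    plain = SwinBlock(32, 4, 4, shifted=False, rng=np.random.default_rng(7))
    shifted = SwinBlock(32, 4, 4, shifted=True, rng=np.random.default_rng(7))
    x = Tensor(np.full((16, 16, 32), 0.37, dtype=np.float32))
    out_p = plain(x)
    out_s = shifted(x)
    assert out_p.shape == (16, 16, 32)
    # a cyclic shift is a bijection on a constant field: same output
    assert np.allclose(out_p.data, out_s.data, atol=1e-5)


def test_shifted_attention_mask_zeroes_cross_zone_weights():
    """Attention probability across non-adjacent pre-shift zones is 0."""
    rng = np.random.default_rng(5)
    block = SwinBlock(8, 2, 4, shifted=True, rng=rng)
    block.attn.store_attn = True
    x = Tensor(rng.standard_normal((8, 8, 8)).astype(np.float32))
    block(x)
    probs = block.attn.last_attn  # (nW, heads, N, N)
    labels = shift_zone_labels(8, 8, 4, 2)
    labels = np.roll(labels, (-2, -2), axis=(0, 1))
    win = window_partition(labels[:, :, None].astype(float), 4).reshape(-1, 16)
    for w in range(probs.shape[0]):
        same = win[w][:, None] == win[w][None, :]
        assert np.all(probs[w][:, ~same] == 0.0)
        rows = probs[w].sum(axis=-1)
        assert np.allclose(rows, 1.0, atol=1e-6)


def test_patch_merge_shapes_and_averaging_projection():
    rng = np.random.default_rng(0)
    pm = PatchMerge(3, rng)
    x = Tensor(np.arange(2 * 2 * 3, dtype=np.float32).reshape(2, 2, 3))
    assert pm(x).shape == (1, 1, 6)
    # averaging projection maps a constant field to the same constant
    pm.reduction.weight.data[:] = 0
    for out_c in range(6):
        for block in range(4):
            pm.reduction.weight.data[block * 3 + out_c % 3, out_c] = 0.25
    const = Tensor(np.full((4, 4, 3), 1.7, dtype=np.float32))
    out = pm(const)
    assert np.allclose(out.data, 1.7, atol=1e-6)


@pytest.mark.parametrize("size,shapes", [
    (256, [(32, 32, 64), (16, 16, 128), (8, 8, 256)]),
])
def test_backbone_stride_arithmetic_tiny(size, shapes):
    bb = SwinBackbone(BackboneConfig.tiny(), seed=0)
    with T.no_grad():
        feats = bb(np.zeros((size, size, 3), dtype=np.uint8))
    assert [f.shape for f in feats] == shapes
    assert [f.stride for f in feats] == [8, 16, 32]


def test_backbone_depth_does_not_change_shapes():
    cfg_a = BackboneConfig(embed_dim=32, depths=(2, 2, 2, 2),
                           num_heads=(2, 4, 8, 8), attn_window=4, mlp_ratio=2.0)
    cfg_b = BackboneConfig(embed_dim=32, depths=(2, 2, 4, 2),
                           num_heads=(2, 4, 8, 8), attn_window=4, mlp_ratio=2.0)
    img = np.zeros((128, 128, 3), dtype=np.uint8)
    with T.no_grad():
        sa = [f.shape for f in SwinBackbone(cfg_a, seed=0)(img)]
        sb = [f.shape for f in SwinBackbone(cfg_b, seed=0)(img)]
    assert sa == sb


def test_backbone_rejects_bad_divisibility():
    bb = SwinBackbone(BackboneConfig.tiny(), seed=0)
    with pytest.raises(ValueError, match="not divisible"):
        bb(np.zeros((100, 128, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        BackboneConfig(depths=(2, 3, 2, 2))


def test_backbone_gradient_reaches_embedding():
    """A loss on feat3 must produce nonzero embedding gradients."""
    bb = SwinBackbone(BackboneConfig.tiny(), seed=1)
    f1, f2, f3 = bb(np.full((128, 128, 3), 90, dtype=np.uint8))
    (f3.data * f3.data).mean().backward()
    assert np.abs(bb.embed.proj.weight.grad).max() > 0
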