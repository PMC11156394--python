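"""SCF neck: unfold/autocorrelation oracles, residual identity, pyramid."""

import numpy as np
import pytest

from pestdet import _tensor as T
from pestdet._tensor import Tensor
from pestdet.backbone import FeatureMap
from pestdet.scf_fpn import (SCFConfig, SCFModule, SCFNeck, autocorrelation,
                             autocorrelation_reference, neighborhood_unfold,
                             unfold_reference)


def test_scf_config_validation_and_uniform_ablation():
    cfg = SCFConfig()
    assert cfg.windows == ((7, 7), (5, 5), (3, 3))
    assert SCFConfig.uniform(5).windows == ((5, 5), (5, 5), (5, 5))
    with pytest.raises(ValueError):
        SCFConfig(windows=((4, 4), (5, 5), (3, 3)))
    with pytest.raises(ValueError):
        SCFConfig(neck_channels=0)


def test_neighborhood_unfold_shape_and_padding():
    x = np.full((4, 4, 2), 3.0, dtype=np.float32)
    R = neighborhood_unfold(x, 3, 3).data
    assert R.shape == (4, 4, 3, 3, 2)
    # interior entries equal the constant; out-of-bounds entries are 0
    assert np.all(R[1:3, 1:3] == 3.0)
    assert np.all(R[0, 0, 0, 0] == 0.0)  # top-left corner looks outside
    assert np.all(R[0, 0, 1, 1] == 3.0)  # centre tap


def test_neighborhood_unfold_matches_loop_oracle():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((6, 5, 3)).astype(np.float32)
    R = neighborhood_unfold(x, 3, 3).data
    assert np.array_equal(R, unfold_reference(x, 3, 3))
    R5 = neighborhood_unfold(x, 5, 3).data
    assert np.array_equal(R5, unfold_reference(x, 5, 3))


def test_neighborhood_unfold_rejects_even_windows():
    with pytest.raises(ValueError, match="odd"):
        neighborhood_unfold(np.zeros((4, 4, 1), dtype=np.float32), 2, 3)


def test_autocorrelation_identity_and_annihilation():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((5, 4, 2)).astype(np.float32)
    ones = np.ones_like(x)
    R = neighborhood_unfold(Tensor(ones), 3, 3)
    D = autocorrelation(R, Tensor(ones)).data
    assert np.array_equal(D, R.data.reshape(5, 4, -1))  # X == 1: D == flat R
    zeros = Tensor(np.zeros_like(x))
    D0 = autocorrelation(neighborhood_unfold(zeros, 3, 3), zeros).data
    assert np.all(D0 == 0.0)


def test_autocorrelation_matches_pointwise_oracle():
    """D[i,j,(u*V+v)*C+c] == X[i+du, j+dv, c] * X[i,j,c] (rel tol 1e-5)."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal((6, 5, 3)).astype(np.float32)
    xt = Tensor(x)
    D = autocorrelation(neighborhood_unfold(xt, 3, 3), xt).data
    ref = autocorrelation_reference(x, 3, 3)
    assert np.allclose(D, ref, rtol=1e-5, atol=1e-7)


def test_embed_fuse_residual_identity_is_bit_exact():
    """Zero-initialised SCF projections leave A == X to 0 ulp."""
    rng = np.random.default_rng(0)
    scf = SCFModule(8, 4, (3, 3), rng)
    x = Tensor(rng.standard_normal((6, 6, 4)).astype(np.float32))
    D = autocorrelation(neighborhood_unfold(x, 3, 3), x)
    A = scf.fuse(x, D)
    assert np.array_equal(A.data, x.data)


def test_embed_fuse_channel_arithmetic():
    rng = np.random.default_rng(0)
    scf = SCFModule(16, 256, (3, 3), rng)
    # G = [X; D]: 256 + 9*256 = 2560 input channels on the first projection
    assert scf.fuse.proj1.weight.shape == (2560, 256)


def test_embed_fuse_affine_composition_on_toy_grid():
    """With fixed weights, fuse(X, D) equals the hand-built affine map."""
    rng = np.random.default_rng(4)
    scf = SCFModule(2, 2, (3, 3), rng)
    W1 = rng.standard_normal((2 + 18, 2)).astype(np.float32) * 0.1
    b1 = rng.standard_normal(2).astype(np.float32) * 0.1
    W2 = rng.standard_normal((2, 2)).astype(np.float32) * 0.1
    b2 = rng.standard_normal(2).astype(np.float32) * 0.1
    scf.fuse.proj1.weight.data = W1
    scf.fuse.proj1.bias.data = b1
    scf.fuse.proj2.weight.data = W2
    scf.fuse.proj2.bias.data = b2
    x = rng.standard_normal((2, 2, 2)).astype(np.float32)
    D = autocorrelation_reference(x, 3, 3)
    G = np.concatenate([x, D], axis=-1)
    expected = x + ((G @ W1 + b1) @ W2 + b2)
    xt = Tensor(x)
    got = scf.fuse(xt, autocorrelation(neighborhood_unfold(xt, 3, 3), xt))
    assert np.allclose(got.data, expected, rtol=1e-5, atol=1e-6)


def test_scf_enhance_output_shapes():
    neck = SCFNeck(in_channels=(32, 64, 128),
                   config=SCFConfig(neck_channels=16), seed=0)
    rng = np.random.default_rng(0)
    f1 = FeatureMap(Tensor(rng.standard_normal((16, 16, 32)).astype(np.float32)), 8)
    f3 = FeatureMap(Tensor(rng.standard_normal((4, 4, 128)).astype(np.float32)), 32)
    assert neck.enhance(f1, 1).shape == (16, 16, 16)
    assert neck.enhance(f3, 3).shape == (4, 4, 16)
    with pytest.raises(ValueError):
        neck.enhance(f1, 0)


def test_pyramid_shapes_and_channels():
    neck = SCFNeck(in_channels=(32, 64, 128),
                   config=SCFConfig(neck_channels=16), seed=0)
    rng = np.random.default_rng(1)
    feats = [FeatureMap(Tensor(rng.standard_normal(s).astype(np.float32)), st)
             for s, st in [((32, 32, 32), 8), ((16, 16, 64), 16),
                           ((8, 8, 128), 32)]]
    with T.no_grad():
        P3, P4, P5, P6 = neck(tuple(feats))
    assert [p.shape[:2] for p in (P3, P4, P5, P6)] == [
        (32, 32), (16, 16), (8, 8), (4, 4)]
    assert all(p.channels == 16 for p in (P3, P4, P5, P6))
    assert [p.stride for p in (P3, P4, P5, P6)] == [8, 16, 32, 64]


def test_pyramid_zero_lateral_gives_bias_only_p4():
    neck = SCFNeck(in_channels=(8, 8, 8), config=SCFConfig(neck_channels=4),
                   seed=3)
    z = Tensor(np.zeros((8, 8, 4), dtype=np.float32))
    A1 = FeatureMap(Tensor(np.zeros((16, 16, 4), dtype=np.float32)), 8)
    A2, A3 = FeatureMap(z, 16), FeatureMap(Tensor(np.zeros((4, 4, 4),
                                                           dtype=np.float32)), 32)
    with T.no_grad():
        P3, P4, P5, P6 = neck.build_pyramid(A1, A2, A3)
    # all-zero inputs leave only the smoothing conv biases
    assert np.allclose(P4.data.data, neck.smooth[1].bias.data, atol=1e-7)
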