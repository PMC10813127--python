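"""Stage-1 feature-distillation operations: worked examples and invariants."""

import numpy as np
import pytest

from dspkd import featdistill as fd


# ---------------------------------------------------------------------------
# adapters
# ---------------------------------------------------------------------------

def test_identity_adapter_returns_input_unchanged():
    f = np.random.default_rng(0).normal(size=(8, 4, 4)).astype(np.float32)
    out = fd.adapt_student_features(f, fd.AdapterConfig(8, 8))
    assert out is f or np.array_equal(out, f)


def test_channel_adapter_changes_channels_only():
    f = np.random.default_rng(0).normal(size=(8, 5, 7)).astype(np.float32)
    out = fd.adapt_student_features(f, fd.AdapterConfig(8, 16))
    assert out.shape == (16, 5, 7)


def test_one_by_one_adapter_hand_computed():
    cfg = fd.AdapterConfig(1, 1)
    assert cfg.kind == "identity"
    cfg = fd.AdapterConfig(1, 2)
    adapter = fd.FeatureAdapter(cfg)
    adapter.conv.weight.value[:] = np.array([[2.0], [3.0]], dtype=np.float32)
    adapter.conv.bias.value[:] = 0.0
    out = fd.adapt_student_features(np.full((1, 1, 1), 3.0, np.float32), cfg, adapter)
    assert np.allclose(out.ravel(), [6.0, 9.0])


def test_adapter_channel_mismatch_raises():
    with pytest.raises(ValueError):
        fd.adapt_student_features(np.zeros((4, 2, 2)), fd.AdapterConfig(8, 8))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_orig_feature_loss_examples():
    t = np.ones((1, 2, 2))
    assert fd.orig_feature_loss(t, t) == 0.0
    assert fd.orig_feature_loss(np.full((1, 1, 1), 3.0), np.full((1, 1, 1), 2.0)) == 1.0
    s = np.array([[[0.0, 1.0], [2.0, 3.0]]])
    assert fd.orig_feature_loss(s, t) == 6.0
    with pytest.raises(ValueError):
        fd.orig_feature_loss(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


def test_stage1_loss_examples():
    t = np.full((1, 1, 1), 3.0)
    g = np.full((1, 1, 1), 2.0)
    cfg = fd.Stage1Config(alpha=0.5)
    out = fd.stage1_loss(g, t, t, cfg)
    assert out["total"] == pytest.approx(0.5)
    assert out["reconstruction"] == pytest.approx(1.0)
    assert out["orig"] == 0.0
    # alpha = 0 reduces to the plain mimicry loss
    s = np.full((1, 1, 1), 1.0)
    out = fd.stage1_loss(g, t, s, fd.Stage1Config(alpha=0.0))
    assert out["total"] == fd.orig_feature_loss(s, t)
    # exact coincidence gives zero
    out = fd.stage1_loss(t, t, t, cfg)
    assert out["total"] == 0.0
    with pytest.raises(ValueError):
        fd.Stage1Config(alpha=-1.0)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_random_mask_extremes_and_concentration():
    assert fd.random_mask(4, 4, 0.0, seed=0).min() == 1.0
    assert fd.random_mask(4, 4, 1.0, seed=0).max() == 0.0
    m = fd.random_mask(100, 100, 0.3, seed=5)
    zero_frac = 1.0 - m.mean()
    assert 0.25 <= zero_frac <= 0.35
    assert np.array_equal(m, fd.random_mask(100, 100, 0.3, seed=5))
    with pytest.raises(ValueError):
        fd.random_mask(4, 4, 1.5, seed=0)


def test_guided_mask_threshold_example():
    a = np.array([[0.9, 0.1], [0.4, 0.6]])
    cfg = fd.Stage1Config(mask_mode="threshold", phi_or_ratio=0.5)
    assert np.array_equal(fd.guided_mask(a, cfg), [[0, 1], [1, 0]])
    # phi = 1.0 zeroes only the maximal positions of a rescaled map
    cfg = fd.Stage1Config(mask_mode="threshold", phi_or_ratio=1.0)
    assert np.array_equal(fd.guided_mask(a / a.max() if a.max() != 1 else a, cfg),
                          [[0, 1], [1, 1]])


def test_guided_mask_ratio_example_and_tiebreak():
    a = np.array([[0.9, 0.1], [0.4, 0.6]])
    cfg = fd.Stage1Config(mask_mode="ratio", phi_or_ratio=0.25)
    assert np.array_equal(fd.guided_mask(a, cfg), [[0, 1], [1, 1]])
    # ties resolved in row-major order
    tied = np.full((2, 2), 0.5)
    m = fd.guided_mask(tied, fd.Stage1Config(mask_mode="ratio", phi_or_ratio=0.5))
    assert np.array_equal(m, [[0, 0], [1, 1]])


def test_guided_mask_threshold_matches_brute_force_scan():
    rng = np.random.default_rng(42)
    for _ in range(20):
        a = rng.random((8, 8))
        phi = float(rng.uniform(0.1, 1.0))
        m = fd.guided_mask(a, fd.Stage1Config(mask_mode="threshold", phi_or_ratio=phi))
        for h in range(8):
            for w in range(8):
                assert m[h, w] == (0.0 if a[h, w] >= phi else 1.0)


def test_guided_mask_ratio_fraction_within_tolerance():
    rng = np.random.default_rng(3)
    for ratio in (0.1, 0.33, 0.5, 0.77):
        a = rng.random((8, 8))  # continuous, ties have probability zero
        m = fd.guided_mask(a, fd.Stage1Config(mask_mode="ratio", phi_or_ratio=ratio))
        assert abs((1.0 - m.mean()) - ratio) <= 1.0 / 64 + 1e-12


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def test_level_attention_examples():
    assert np.array_equal(fd.level_attention(np.full((3, 2, 2), 7.0)), np.zeros((2, 2)))
    f = np.zeros((1, 3, 3))
    f[0, 1, 2] = 5.0
    att = fd.level_attention(f)
    assert att[1, 2] == 1.0 and att.sum() == 1.0
    # two channels: |a|=(1,3), |b|=(5,1) -> means (2,3) -> rescaled (0,1)
    f = np.array([[[1.0, 5.0]], [[3.0, -1.0]]])
    assert np.allclose(fd.level_attention(f), [[0.0, 1.0]])


def test_hf_fuse_single_level_and_hand_example():
    a = np.random.default_rng(0).random((4, 4))
    assert np.allclose(fd.hf_fuse([a]), a / a.max())
    shallow = np.array([[1.0, 0.0], [0.0, 0.0]])
    deep = np.array([[1.0]])
    fused = fd.hf_fuse([shallow, deep], weights=[0.5, 0.5])
    assert np.allclose(fused, [[1.0, 0.5], [0.5, 0.5]])


def test_hf_fuse_invariant_to_common_positive_rescaling():
    rng = np.random.default_rng(1)
    levels = [rng.random((16, 16)), rng.random((8, 8)), rng.random((4, 4)), rng.random((2, 2))]
    base = fd.hf_fuse(levels)
    scaled = fd.hf_fuse([7.3 * lvl for lvl in levels])
    assert np.allclose(base, scaled, atol=1e-12)


def test_hf_fuse_error_cases():
    with pytest.raises(ValueError):
        fd.hf_fuse([])
    with pytest.raises(ValueError):
        fd.hf_fuse([np.ones((2, 2)), np.ones((2, 2))])  # not shrinking
    with pytest.raises(ValueError):
        fd.hf_fuse([np.ones((4, 4)), np.ones((2, 2))], weights=[1.0])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def test_generate_features_mask_contracts():
    rng = np.random.default_rng(0)
    block = fd.GenerationBlock(2, activation="gelu", seed=0)
    f = rng.normal(size=(2, 4, 4)).astype(np.float32)
    ones = np.ones((4, 4), dtype=np.float32)
    direct = block.forward(f[None], train=False)[0]
    assert np.allclose(fd.generate_features(f, ones, block), direct)
    # all-zeros mask: output independent of the input values
    zeros = np.zeros((4, 4), dtype=np.float32)
    out1 = fd.generate_features(f, zeros, block)
    out2 = fd.generate_features(10.0 + f, zeros, block)
    assert np.allclose(out1, out2)
    with pytest.raises(ValueError):
        fd.generate_features(f, np.ones((3, 3)), block)


def test_generate_features_masked_position_is_silenced():
    """A masked position contributes nothing to the convolution input."""
    block = fd.GenerationBlock(1, activation="gelu", seed=1)
    mask = np.array([[0.0, 1.0], [1.0, 1.0]], dtype=np.float32)
    f1 = np.arange(4, dtype=np.float32).reshape(1, 2, 2)
    f2 = f1.copy()
    f2[0, 0, 0] = 99.0  # differs only at the masked position
    assert np.allclose(fd.generate_features(f1, mask, block),
                       fd.generate_features(f2, mask, block))


def test_masking_zeroes_reconstruction_gradient():
    """Finite differences: masked positions receive no reconstruction gradient."""
    block = fd.GenerationBlock(1, activation="gelu", seed=2)
    mask = np.array([[0.0, 1.0], [1.0, 1.0]], dtype=np.float32)
    target = np.random.default_rng(0).normal(size=(1, 2, 2)).astype(np.float32)
    f = np.random.default_rng(1).normal(size=(1, 2, 2)).astype(np.float32)

    def recon_loss(feat):
        g = fd.generate_features(feat, mask, block)
        return float(np.sum((g - target) ** 2))

    eps = 1e-2
    bumped = f.copy()
    bumped[0, 0, 0] += eps
    assert recon_loss(bumped) == pytest.approx(recon_loss(f), abs=1e-12)
    bumped = f.copy()
    bumped[0, 1, 1] += eps
    assert recon_loss(bumped) != pytest.approx(recon_loss(f), abs=1e-9)


def test_mgd_loss_determinism_and_hand_traced_toy():
    rng = np.random.default_rng(0)
    f_s = rng.normal(size=(1, 4, 4)).astype(np.float32)
    f_t = rng.normal(size=(1, 4, 4)).astype(np.float32)
    block = fd.GenerationBlock(1, activation="relu", seed=3)
    l1 = fd.mgd_loss(f_s, f_t, 0.5, seed=9, block=block)
    l2 = fd.mgd_loss(f_s, f_t, 0.5, seed=9, block=block)
    assert l1 == l2 and l1 >= 0
    # mask_prob 0: loss equals the squared error of the block output
    g = block.forward(f_s[None], train=False)[0]
    expected = float(np.sum((g.astype(np.float64) - f_t) ** 2))
    assert fd.mgd_loss(f_s, f_t, 0.0, seed=0, block=block) == pytest.approx(expected, rel=1e-6)
    # hand-traced 1x1x1 toy: conv(3x3,pad 1) sees only the center weight
    toy = fd.GenerationBlock(1, activation="relu", seed=0)
    for conv in (toy.net.layers[0], toy.net.layers[2]):
        conv.weight.value[:] = 0.0
        conv.weight.value[0, 4] = 2.0  # center of the 3x3 kernel
        conv.bias.value[:] = 1.0
    f = np.full((1, 1, 1), 1.5, np.float32)
    t = np.full((1, 1, 1), 5.0, np.float32)
    # 1.5 -> conv: 2*1.5+1=4 -> relu 4 -> conv: 2*4+1=9 -> (9-5)^2 = 16
    assert fd.mgd_loss(f, t, 0.0, seed=0, block=toy) == pytest.approx(16.0, rel=1e-6)
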