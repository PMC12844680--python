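"""Cross-modal fusion: attention oracle, residual identity, dynamic weights."""

import numpy as np
import pytest

from crownseg.encoder import FeaturePyramid
from crownseg.fusion import CIF, CotSR, FusionConfig, WeightFusion
from crownseg.nn.tensor import Tensor


def _brute_force_cotsr(x1, x2, gamma1, gamma2):
    """Direct evaluation with identity projections: softmax over key
    positions of Q.K scores, value-weighted sum, residual with gamma."""
    b, c, h, w = x1.shape
    n = h * w
    q1 = x1.reshape(b, c, n)
    k2 = x2.reshape(b, c, n)
    v2 = x2.reshape(b, c, n)
    out = np.empty_like(x1)
    y2 = np.empty_like(x2)
    for bi in range(b):
        s = q1[bi].T @ k2[bi]                       # (N, N)
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        out[bi] = (v2[bi] @ a.T).reshape(c, h, w)
        # symmetric direction
        s2 = x2.reshape(b, c, n)[bi].T @ x1.reshape(b, c, n)[bi]
        e2 = np.exp(s2 - s2.max(axis=1, keepdims=True))
        a2 = e2 / e2.sum(axis=1, keepdims=True)
        y2[bi] = (x1.reshape(b, c, n)[bi] @ a2.T).reshape(c, h, w)
    return x1 + gamma1 * out, x2 + gamma2 * y2


def _identity_cotsr(channels, gamma):
    block = CotSR(channels, qk_reduction=1, gamma_init=gamma,
                  rng=np.random.default_rng(0))
    block.set_identity_projections()
    return block


def test_zero_gamma_is_exact_residual_identity():
    rng = np.random.default_rng(0)
    x1 = Tensor(rng.standard_normal((2, 6, 3, 3)).astype(np.float32))
    x2 = Tensor(rng.standard_normal((2, 6, 3, 3)).astype(np.float32))
    block = CotSR(6, rng=np.random.default_rng(1), gamma_init=0.0)
    y1, y2 = block(x1, x2)
    np.testing.assert_array_equal(y1.data, x1.data)
    np.testing.assert_array_equal(y2.data, x2.data)


def test_single_position_hand_example():
    # 1x1 spatial toy: softmax of a single score is 1, so each output is
    # the residual plus gamma times the other branch's value
    x1 = Tensor(np.full((1, 1, 1, 1), 2.0, dtype=np.float32))
    x2 = Tensor(np.full((1, 1, 1, 1), 3.0, dtype=np.float32))
    block = _identity_cotsr(1, gamma=1.0)
    y1, y2 = block(x1, x2)
    assert y1.data.item() == pytest.approx(5.0, abs=1e-6)
    assert y2.data.item() == pytest.approx(5.0, abs=1e-6)


def test_two_by_two_matches_brute_force():
    rng = np.random.default_rng(3)
    x1 = rng.standard_normal((2, 3, 2, 2)).astype(np.float32)
    x2 = rng.standard_normal((2, 3, 2, 2)).astype(np.float32)
    block = _identity_cotsr(3, gamma=1.0)
    y1, y2 = block(Tensor(x1), Tensor(x2))
    e1, e2 = _brute_force_cotsr(x1, x2, 1.0, 1.0)
    np.testing.assert_allclose(y1.data, e1, atol=1e-6)
    np.testing.assert_allclose(y2.data, e2, atol=1e-6)


def test_attention_rows_are_distributions():
    rng = np.random.default_rng(4)
    block = CotSR(8, rng=np.random.default_rng(5))
    x1 = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32) * 3)
    x2 = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32) * 3)
    block(x1, x2)
    for attn in block.last_attention:
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert (attn >= 0).all()


def test_shape_mismatch_rejected():
    block = CotSR(4, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="disagree"):
        block(Tensor(np.zeros((1, 4, 2, 2), np.float32)),
              Tensor(np.zeros((1, 4, 3, 3), np.float32)))


# -- dynamic weight fusion -------------------------------------------------

def test_weight_fusion_limits_and_arithmetic():
    unit = np.ones((1, 2, 2, 2), dtype=np.float32)
    f = WeightFusion(alpha_init=1.0, beta_init=0.0)
    np.testing.assert_array_equal(
        f(Tensor(2 * unit), Tensor(7 * unit)).data, 2 * unit)
    f = WeightFusion(alpha_init=0.5, beta_init=0.5)
    np.testing.assert_allclose(
        f(Tensor(2 * unit), Tensor(4 * unit)).data, 3 * unit, rtol=1e-6)


def test_weight_fusion_with_reported_trained_values():
    # trained stage weights reported for the deepest fusion stages:
    # alpha 1.107 (RGB), beta 0.971 (MS) at the feat4 stage
    unit = np.ones((1, 3, 2, 2), dtype=np.float32)
    f = WeightFusion(alpha_init=1.107, beta_init=0.971)
    np.testing.assert_allclose(f(Tensor(unit), Tensor(unit)).data,
                               2.078 * unit, rtol=1e-6)


def test_weight_fusion_shape_mismatch():
    f = WeightFusion()
    with pytest.raises(ValueError, match="disagree"):
        f(Tensor(np.zeros((1, 2, 2, 2), np.float32)),
          Tensor(np.zeros((1, 3, 2, 2), np.float32)))


# -- CIF composition -------------------------------------------------------

def _toy_pyramids(rng, channels=(8, 16)):
    sizes = {"feat4": 4, "feat5": 2}
    chans = {"feat4": channels[0], "feat5": channels[1]}
    mk = lambda: {k: Tensor(rng.standard_normal(
        (2, chans[k], sizes[k], sizes[k])).astype(np.float32)) for k in sizes}
    return (FeaturePyramid(mk(), "rgb"), FeaturePyramid(mk(), "ms"), chans)


def test_cif_identity_composition_passes_rgb_through():
    rng = np.random.default_rng(6)
    rgb_pyr, ms_pyr, chans = _toy_pyramids(rng)
    cif = CIF(chans, FusionConfig(gamma_init=0.0, alpha_init=1.0,
                                  beta_init=0.0), rng=np.random.default_rng(7))
    fused = cif(rgb_pyr, ms_pyr)
    for stage in ("feat4", "feat5"):
        np.testing.assert_allclose(fused[stage].data, rgb_pyr[stage].data,
                                   atol=1e-7)
        assert fused[stage].shape == rgb_pyr[stage].shape


def test_cif_stage_parameters_are_independent():
    rng = np.random.default_rng(8)
    rgb_pyr, ms_pyr, chans = _toy_pyramids(rng)
    cif = CIF(chans, FusionConfig(), rng=np.random.default_rng(9))
    before = cif(rgb_pyr, ms_pyr)["feat4"].data.copy()
    cif.fusers["feat5"].alpha.data = np.float32(7.0)   # perturb other stage
    after = cif(rgb_pyr, ms_pyr)["feat4"].data
    np.testing.assert_array_equal(before, after)


def test_gradient_reaches_gamma_alpha_beta():
    rng = np.random.default_rng(10)
    rgb_pyr, ms_pyr, chans = _toy_pyramids(rng)
    cif = CIF(chans, FusionConfig(gamma_init=0.5), rng=np.random.default_rng(11))
    fused = cif(rgb_pyr, ms_pyr)
    loss = (fused["feat4"] * fused["feat4"]).sum() + \
           (fused["feat5"] * fused["feat5"]).sum()
    loss.backward()
    for stage in ("feat4", "feat5"):
        for p in (cif.cotsr[stage].gamma1, cif.cotsr[stage].gamma2,
                  cif.fusers[stage].alpha, cif.fusers[stage].beta):
            assert p.grad is not None and abs(float(p.grad)) > 0


def test_cif_missing_level_rejected():
    rng = np.random.default_rng(12)
    rgb_pyr, ms_pyr, chans = _toy_pyramids(rng)
    cif = CIF(chans, FusionConfig(), rng=np.random.default_rng(13))
    del ms_pyr.levels["feat5"]
    with pytest.raises(KeyError, match="feat5"):
        cif(rgb_pyr, ms_pyr)
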