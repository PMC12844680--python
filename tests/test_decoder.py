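"""Attention-enhanced decoder: CBAM bounds and oracles, Up-Concat contracts."""

import numpy as np
import pytest

from crownseg.decoder import (
    CBAM,
    ChannelAttention,
    Decoder,
    DecoderConfig,
    SpatialAttention,
    UpConcat,
)
from crownseg.nn.tensor import Tensor


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def test_channel_attention_bounds_and_divisibility():
    rng = np.random.default_rng(0)
    ca = ChannelAttention(8, reduction=4, rng=np.random.default_rng(1))
    mc = ca(Tensor(rng.standard_normal((3, 8, 5, 5)).astype(np.float32)))
    assert mc.shape == (3, 8)
    assert (mc.data > 0).all() and (mc.data < 1).all()
    with pytest.raises(ValueError, match="divisible"):
        ChannelAttention(10, reduction=4, rng=np.random.default_rng(2))


def test_channel_attention_constant_input_hand_evaluation():
    # spatially constant input: avg pool equals max pool, so the channel
    # map is sigmoid(2 * MLP(c)); evaluate the MLP directly to cross-check
    ca = ChannelAttention(4, reduction=2, rng=np.random.default_rng(3))
    const = np.array([0.5, -1.0, 2.0, 0.0], dtype=np.float32)
    x = np.broadcast_to(const[None, :, None, None], (1, 4, 6, 6)).astype(np.float32)
    mc = ca(Tensor(x.copy()))
    w1, b1 = ca.fc1.weight.data, ca.fc1.bias.data
    w2, b2 = ca.fc2.weight.data, ca.fc2.bias.data
    hidden = np.maximum(const @ w1 + b1, 0.0)
    expected = _expit(2.0 * (hidden @ w2 + b2))
    np.testing.assert_allclose(mc.data[0], expected, rtol=1e-5, atol=1e-6)


def test_spatial_attention_constant_and_single_pixel():
    sa = SpatialAttention(7, rng=np.random.default_rng(4))
    const = np.full((1, 3, 9, 9), 0.7, dtype=np.float32)
    ms = sa(Tensor(const))
    assert ms.shape == (1, 1, 9, 9)
    assert (ms.data > 0).all() and (ms.data < 1).all()
    # interior of a constant plane is exactly constant (same-padding edges
    # differ); interior excludes the 3-pixel border of the 7x7 kernel
    interior = ms.data[0, 0, 3:-3, 3:-3]
    np.testing.assert_allclose(interior, interior.flat[0], atol=1e-6)
    # 1x1 input: response is sigmoid of the kernel center acting on [avg;max]
    x = np.full((1, 3, 1, 1), -0.4, dtype=np.float32)
    out = sa(Tensor(x))
    k = sa.conv.weight.data          # (1, 2, 7, 7)
    center = k[0, 0, 3, 3] * (-0.4) + k[0, 1, 3, 3] * (-0.4) + sa.conv.bias.data[0]
    assert out.data.item() == pytest.approx(_expit(center), rel=1e-5)


def test_cbam_is_elementwise_contraction_and_preserves_zero():
    rng = np.random.default_rng(5)
    cbam = CBAM(8, reduction=4, rng=np.random.default_rng(6))
    x = rng.standard_normal((2, 8, 6, 6)).astype(np.float32) * 3
    out = cbam(Tensor(x))
    assert out.shape == x.shape
    assert (np.abs(out.data) <= np.abs(x) + 1e-7).all()
    zero = cbam(Tensor(np.zeros((1, 8, 4, 4), np.float32)))
    np.testing.assert_array_equal(zero.data, 0.0)


def test_cbam_sequential_composes_channel_then_spatial():
    rng = np.random.default_rng(7)
    cbam = CBAM(4, reduction=2, rng=np.random.default_rng(8))
    x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
    out = cbam(Tensor(x))
    mc = cbam.channel(Tensor(x)).data.reshape(1, 4, 1, 1)
    refined = x * mc
    ms = cbam.spatial(Tensor(refined)).data
    np.testing.assert_allclose(out.data, refined * ms, rtol=1e-5, atol=1e-6)


def test_cbam_parallel_variant_multiplies_raw_maps():
    rng = np.random.default_rng(9)
    cbam = CBAM(4, reduction=2, order="parallel", rng=np.random.default_rng(10))
    x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
    out = cbam(Tensor(x))
    mc = cbam.channel(Tensor(x)).data.reshape(1, 4, 1, 1)
    ms = cbam.spatial(Tensor(x)).data
    np.testing.assert_allclose(out.data, x * mc * ms, rtol=1e-5, atol=1e-6)


def test_up_concat_shapes_order_and_gradients():
    cfg = DecoderConfig(cbam_reduction=4)
    up = UpConcat(16, 8, 8, cfg, rng=np.random.default_rng(11))
    rng = np.random.default_rng(12)
    deep = Tensor(rng.standard_normal((1, 16, 5, 5)).astype(np.float32),
                  requires_grad=True)
    skip = Tensor(rng.standard_normal((1, 8, 10, 10)).astype(np.float32),
                  requires_grad=True)
    out = up(deep, skip)
    assert out.shape == (1, 8, 10, 10)
    (out * out).sum().backward()
    assert deep.grad is not None and np.abs(deep.grad).max() > 0
    assert skip.grad is not None and np.abs(skip.grad).max() > 0
    # concatenation order (up, skip): swapping inputs changes the output
    bad_skip = Tensor(rng.standard_normal((1, 8, 9, 9)).astype(np.float32))
    with pytest.raises(ValueError, match="does not match"):
        up(deep, bad_skip)


def test_transposed_upsampling_variant():
    cfg = DecoderConfig(cbam_reduction=4, upsample_mode="transposed")
    up = UpConcat(16, 8, 8, cfg, rng=np.random.default_rng(13))
    deep = Tensor(np.random.default_rng(14).standard_normal(
        (2, 16, 4, 4)).astype(np.float32))
    skip = Tensor(np.zeros((2, 8, 8, 8), dtype=np.float32))
    assert up(deep, skip).shape == (2, 8, 8, 8)


@pytest.mark.parametrize("cbam_enabled", [True, False])
def test_decoder_restores_input_resolution(cbam_enabled):
    widths = (8, 16, 32, 64, 128)
    cfg = DecoderConfig(cbam_reduction=4, cbam_enabled=cbam_enabled)
    dec = Decoder(widths, cfg, rng=np.random.default_rng(15))
    rng = np.random.default_rng(16)
    mk = lambda c, s: Tensor(rng.standard_normal((1, c, s, s)).astype(np.float32))
    logits = dec(mk(128, 2), mk(64, 4), mk(32, 8), mk(16, 16), mk(8, 32))
    assert logits.shape == (1, 2, 64, 64)
    # exactly four refinement stages precede the classifier head
    assert [hasattr(dec, f"stage{i}") for i in (1, 2, 3, 4)] == [True] * 4
    assert not hasattr(dec, "stage5")


def test_decoder_rejects_ladder_violation():
    widths = (8, 16, 32, 64, 128)
    dec = Decoder(widths, DecoderConfig(cbam_reduction=4),
                  rng=np.random.default_rng(17))
    rng = np.random.default_rng(18)
    mk = lambda c, s: Tensor(rng.standard_normal((1, c, s, s)).astype(np.float32))
    with pytest.raises(ValueError, match="does not match"):
        dec(mk(128, 2), mk(64, 4), mk(32, 8), mk(16, 16), mk(8, 64))
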