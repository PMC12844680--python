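"""Gradient and contract checks for the autodiff engine.

Every structured primitive used by the segmentation model is validated
against central finite differences on small random inputs, so training-time
gradients are trustworthy by construction.
"""

import numpy as np
import pytest

from crownseg import nn
from crownseg.nn.tensor import Tensor, concat, tmax, tmean


def _numeric_grad(fn, arrays, index, eps=1e-2):
    """Central-difference gradient of scalar fn(*arrays) w.r.t. arrays[index]."""
    base = [a.copy() for a in arrays]
    grad = np.zeros_like(base[index], dtype=np.float64)
    it = np.nditer(base[index], flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        for sign in (+1, -1):
            pert = [a.copy() for a in base]
            pert[index][idx] += sign * eps
            val = fn(*[Tensor(a) for a in pert]).data.item()
            grad[idx] += sign * val
        grad[idx] /= 2 * eps
        it.iternext()
    return grad


def _gradcheck(fn, shapes, seed=0, eps=1e-2, rtol=3e-2, atol=3e-3):
    rng = np.random.default_rng(seed)
    arrays = [rng.standard_normal(s).astype(np.float32) for s in shapes]
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    loss = fn(*tensors)
    loss.backward()
    for k, t in enumerate(tensors):
        num = _numeric_grad(fn, arrays, k, eps=eps)
        assert t.grad is not None, f"no gradient reached input {k}"
        np.testing.assert_allclose(t.grad, num, rtol=rtol, atol=atol,
                                   err_msg=f"analytic/numeric mismatch, input {k}")


@pytest.mark.parametrize("name,fn,shapes", [
    ("add_broadcast", lambda a, b: (a + b).sum(), [(3, 4), (4,)]),
    ("mul_broadcast", lambda a, b: (a * b).mean(), [(2, 3, 2), (3, 1)]),
    ("matmul_batched", lambda a, b: (a @ b).sum(), [(2, 3, 4), (2, 4, 2)]),
    ("sigmoid", lambda a: nn.sigmoid(a).sum(), [(3, 5)]),
    ("gelu", lambda a: nn.gelu(a).sum(), [(4, 4)]),
    ("softmax", lambda a: (nn.softmax(a, axis=-1) * nn.softmax(a, axis=-1)).sum(),
     [(3, 6)]),
    ("mean_axis", lambda a: tmean(a, axis=1).sum(), [(3, 5)]),
    ("concat", lambda a, b: concat([a, b], axis=1).sum(), [(2, 3), (2, 2)]),
    ("conv2d", lambda x, w, b: nn.conv2d(x, w, b, stride=1, padding=1).sum(),
     [(2, 3, 5, 5), (4, 3, 3, 3), (4,)]),
    ("conv2d_strided", lambda x, w: nn.conv2d(x, w, stride=2, padding=0).sum(),
     [(1, 2, 6, 6), (3, 2, 2, 2)]),
    ("depthwise", lambda x, w, b: nn.depthwise_conv2d(x, w, b, padding=2).sum(),
     [(2, 3, 5, 5), (3, 5, 5), (3,)]),
    ("layernorm", lambda x, g, b: (nn.layer_norm_channels(x, g, b) ** 0
                                   if False else
                                   (nn.layer_norm_channels(x, g, b)
                                    * nn.layer_norm_channels(x, g, b)).sum()),
     [(2, 4, 3, 3), (4,), (4,)]),
    ("upsample", lambda x: (nn.upsample_bilinear_2x(x)
                            * nn.upsample_bilinear_2x(x)).sum(), [(1, 2, 4, 4)]),
])
def test_gradcheck(name, fn, shapes):
    _gradcheck(fn, shapes)


def test_gradcheck_max():
    # well-separated values so argmax is stable under the probe step
    rng = np.random.default_rng(1)
    a = (rng.permutation(24).reshape(2, 3, 4) * 1.0).astype(np.float32)

    def fn(t):
        return tmax(t, axis=2).sum()

    t = Tensor(a, requires_grad=True)
    fn(t).backward()
    num = _numeric_grad(lambda u: fn(u), [a], 0, eps=1e-3)
    np.testing.assert_allclose(t.grad, num, atol=1e-3)


def test_gradcheck_cross_entropy():
    rng = np.random.default_rng(2)
    logits = rng.standard_normal((3, 2, 4, 4)).astype(np.float32)
    labels = rng.integers(0, 2, size=(3, 4, 4))

    def fn(t):
        return nn.softmax_cross_entropy(t, labels)

    t = Tensor(logits, requires_grad=True)
    fn(t).backward()
    num = _numeric_grad(fn, [logits], 0, eps=1e-2)
    np.testing.assert_allclose(t.grad, num, rtol=3e-2, atol=3e-3)


def test_cross_entropy_matches_manual_value():
    logits = np.array([[[[2.0]], [[0.0]]]], dtype=np.float32)  # (1,2,1,1)
    labels = np.array([[[1]]])
    loss = nn.softmax_cross_entropy(Tensor(logits), labels)
    expected = -np.log(np.exp(0.0) / (np.exp(2.0) + np.exp(0.0)))
    assert loss.data == pytest.approx(expected, rel=1e-6)


def test_upsample_preserves_constants_and_doubles_size():
    x = Tensor(np.full((1, 1, 3, 5), 7.0, dtype=np.float32))
    y = nn.upsample_bilinear_2x(x)
    assert y.shape == (1, 1, 6, 10)
    np.testing.assert_allclose(y.data, 7.0, rtol=1e-6)


def test_conv2d_shapes_and_channel_mismatch():
    rng = np.random.default_rng(0)
    x = Tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32))
    w = Tensor(rng.standard_normal((5, 3, 3, 3)).astype(np.float32))
    assert nn.conv2d(x, w, padding=1).shape == (1, 5, 8, 8)
    assert nn.conv2d(x, w, stride=2, padding=1).shape == (1, 5, 4, 4)
    bad = Tensor(rng.standard_normal((5, 4, 3, 3)).astype(np.float32))
    with pytest.raises(ValueError, match="channel mismatch"):
        nn.conv2d(x, bad)


def test_softmax_rows_are_distributions():
    rng = np.random.default_rng(3)
    x = Tensor(rng.standard_normal((10, 7)).astype(np.float32) * 10)
    p = nn.softmax(x, axis=-1)
    np.testing.assert_allclose(p.data.sum(axis=-1), 1.0, atol=1e-6)
    assert (p.data >= 0).all()


def test_adam_minimizes_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0], dtype=np.float32))
    opt = nn.Adam([p], lr=0.2)
    for _ in range(200):
        opt.zero_grad()
        loss = (p * p).sum()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_module_state_dict_roundtrip():
    rng = np.random.default_rng(0)
    m = nn.Sequential(
        nn.Conv2d(3, 4, 3, padding=1, rng=rng),
        nn.GELU(),
        nn.Conv2d(4, 2, 1, rng=rng),
    )
    state = m.state_dict()
    m2 = nn.Sequential(
        nn.Conv2d(3, 4, 3, padding=1, rng=np.random.default_rng(9)),
        nn.GELU(),
        nn.Conv2d(4, 2, 1, rng=np.random.default_rng(9)),
    )
    m2.load_state_dict(state)
    x = Tensor(np.random.default_rng(1).standard_normal((1, 3, 6, 6)).astype(np.float32))
    np.testing.assert_array_equal(m(x).data, m2(x).data)
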