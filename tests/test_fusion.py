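"""Fusion core oracles: channel shuffle permutation, grouped affine maps,
CBAM attention arithmetic, gated fusion boundaries, assembled model."""

import numpy as np
import pytest

from dualcmnet import (CBAM, CBAMConfig, GateConfig, GatedFusion,
                       GroupedLinear, HShuffleBlock, HShuffleConfig,
                       build_dualcmnet, channel_shuffle, nn)
from dualcmnet.errors import ConfigurationError, ValidationError
from dualcmnet.spatial import SpatialNetConfig, build_spatial_net
from dualcmnet.spectral import SpectralNetConfig, build_spectral_net
from dualcmnet.training import count_params

from conftest import gradcheck, to_float64


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------


def brute_force_shuffle(x, g):
    """Enumerate the reshape-(g, d/g)-transpose-flatten index map."""
    d = len(x)
    out = np.empty_like(x)
    for j in range(g):          # group
        for k in range(d // g):  # slot within group
            out[k * g + j] = x[j * (d // g) + k]
    return out


def test_channel_shuffle_matches_enumerated_permutation():
    x = np.arange(6.0)[None]
    np.testing.assert_array_equal(channel_shuffle(x, 2)[0],
                                  [0.0, 3.0, 1.0, 4.0, 2.0, 5.0])
    rng = np.random.default_rng(0)
    for d, g in [(6, 2), (12, 3), (16, 8), (8, 1)]:
        x = rng.standard_normal((2, d))
        expected = np.stack([brute_force_shuffle(row, g) for row in x])
        np.testing.assert_array_equal(channel_shuffle(x, g), expected)


def test_channel_shuffle_is_a_bijection():
    rng = np.random.default_rng(1)
    for d, g in [(6, 2), (24, 8), (10, 5)]:
        x = rng.standard_normal((3, d))
        np.testing.assert_array_equal(
            channel_shuffle(channel_shuffle(x, g), d // g), x)
    with pytest.raises(ValueError):
        channel_shuffle(np.zeros((1, 7)), 2)


# ---------------------------------------------------------------------------
# grouped linear
# ---------------------------------------------------------------------------


def test_grouped_linear_single_group_equals_dense():
    gl = GroupedLinear(5, 4, 1)
    x = np.random.default_rng(2).standard_normal((3, 5)).astype(np.float32)
    dense = x @ gl.weight.value[0].T + gl.bias.value
    np.testing.assert_allclose(gl(x), dense, atol=1e-6)


def test_grouped_linear_identity_weights_pass_input_through():
    gl = GroupedLinear(6, 6, 3)
    for i in range(3):
        gl.weight.value[i] = np.eye(2, dtype=np.float32)
    gl.bias.value[...] = 0
    x = np.random.default_rng(3).standard_normal((2, 6)).astype(np.float32)
    np.testing.assert_allclose(gl(x), x, atol=1e-7)


def test_grouped_linear_matches_block_diagonal_oracle():
    gl = GroupedLinear(4, 4, 2)
    x = np.random.default_rng(4).standard_normal((3, 4)).astype(np.float32)
    block = np.zeros((4, 4), np.float32)
    block[:2, :2] = gl.weight.value[0]
    block[2:, 2:] = gl.weight.value[1]
    np.testing.assert_allclose(gl(x), x @ block.T + gl.bias.value, atol=1e-6)


@pytest.mark.parametrize("d1,d2,g", [(8, 4, 2), (16, 8, 8), (6, 6, 3)])
def test_grouped_linear_parameter_count_formula(d1, d2, g):
    gl = GroupedLinear(d1, d2, g)
    assert sum(p.size for p in gl.parameters()) == d1 * d2 // g + d2


def test_grouped_linear_rejects_indivisible_dims():
    with pytest.raises(ValueError):
        GroupedLinear(5, 4, 2)


# ---------------------------------------------------------------------------
# HShuffleBlock
# ---------------------------------------------------------------------------


def test_hshuffle_output_dimension_and_nonnegativity(rng):
    block = HShuffleBlock(HShuffleConfig(in_dim=1024)).eval()
    y = block(rng.standard_normal((3, 1024)).astype(np.float32))
    assert y.shape == (3, 384)
    assert np.all(y >= 0)
    with pytest.raises(ConfigurationError):
        HShuffleConfig(in_dim=1023)


def test_hshuffle_composes_verified_sub_operations(rng):
    """With unit BN statistics in eval mode the block equals the manual
    grouped-affine -> shuffle -> ReLU chain (twice)."""
    cfg = HShuffleConfig(in_dim=8, mid_dim=8, out_dim=8, groups=2)
    block = HShuffleBlock(cfg).eval()
    gl1, sh1, bn1 = block.net.layers[0], block.net.layers[1], block.net.layers[2]
    gl2 = block.net.layers[4]
    x = rng.standard_normal((4, 8)).astype(np.float32)
    eps = bn1.eps
    stage1 = np.maximum(channel_shuffle(gl1(x), 2) / np.sqrt(1 + eps), 0)
    manual = np.maximum(channel_shuffle(gl2(stage1), 2) / np.sqrt(1 + eps), 0)
    np.testing.assert_allclose(block(x), manual, atol=1e-5)


# ---------------------------------------------------------------------------
# CBAM
# ---------------------------------------------------------------------------


def cbam_loop_oracle(cbam, F):
    """Direct loop evaluation of channel-then-spatial attention."""
    N, C, H, W = F.shape
    w1, w2 = cbam.w1.value, cbam.w2.value
    conv_w = cbam.conv.weight.value[0]
    conv_b = cbam.conv.bias.value[0]
    k = conv_w.shape[-1]
    out = np.zeros_like(F)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    for n in range(N):
        zavg = np.array([F[n, c].mean() for c in range(C)])
        zmax = np.array([F[n, c].max() for c in range(C)])
        mlp = lambda z: w2 @ np.maximum(w1 @ z, 0)
        mc = sig(mlp(zavg) + mlp(zmax))
        F1 = F[n] * mc[:, None, None]
        savg = F1.mean(0)
        smax = F1.max(0)
        s = np.stack([savg, smax])
        pad = k // 2
        sp = np.pad(s, ((0, 0), (pad, pad), (pad, pad)))
        for i in range(H):
            for j in range(W):
                resp = (conv_w * sp[:, i:i + k, j:j + k]).sum() + conv_b
                out[n, :, i, j] = F1[:, i, j] * sig(resp)
    return out


def test_cbam_matches_loop_oracle(rng):
    cbam = CBAM(CBAMConfig(channels=4, reduction=2, spatial_kernel=3))
    F = rng.standard_normal((2, 4, 2, 2)).astype(np.float32)
    np.testing.assert_allclose(cbam(F), cbam_loop_oracle(cbam, F), atol=1e-5)


def test_cbam_attention_weights_strictly_in_unit_interval(rng):
    cbam = CBAM(CBAMConfig(channels=8, reduction=2))
    F = rng.standard_normal((3, 8, 2, 2)).astype(np.float32)
    mc = cbam.channel_attention(F)
    ms = cbam.spatial_attention(F)
    assert np.all((mc > 0) & (mc < 1))
    assert np.all((ms > 0) & (ms < 1))


def test_cbam_pooling_degeneracies(rng):
    cbam = CBAM(CBAMConfig(channels=4, reduction=2))
    # spatially constant input: avg == max pooling, so Mc = sigmoid(2 MLP(z))
    z = rng.standard_normal((2, 4)).astype(np.float32)
    F = np.broadcast_to(z[:, :, None, None], (2, 4, 3, 3)).copy()
    _, _, a = cbam._mlp(z)
    np.testing.assert_allclose(cbam.channel_attention(F),
                               1 / (1 + np.exp(-2 * a)), atol=1e-6)
    # zero MLP weights: every channel weight is sigmoid(0) = 0.5
    cbam.w1.value[...] = 0
    cbam.w2.value[...] = 0
    np.testing.assert_allclose(cbam.channel_attention(F), 0.5, atol=1e-7)


def test_cbam_zero_input_gives_zero_output():
    cbam = CBAM(CBAMConfig(channels=4, reduction=2))
    out = cbam(np.zeros((1, 4, 2, 2), np.float32))
    np.testing.assert_array_equal(out, 0.0)


def test_cbam_single_pixel_extent_reduces_to_center_tap(rng):
    """H = W = 1 (the vector-feature case): the spatial weight is the
    sigmoid of the 7x7 kernel's centre tap response plus bias."""
    cbam = CBAM(CBAMConfig(channels=4, reduction=2, spatial_kernel=7))
    F = rng.standard_normal((2, 4, 1, 1)).astype(np.float32)
    ms = cbam.spatial_attention(F)
    centre = cbam.conv.weight.value[0, :, 3, 3]
    resp = (np.stack([F[:, :, 0, 0].mean(1), F[:, :, 0, 0].max(1)], 1)
            * centre).sum(1) + cbam.conv.bias.value[0]
    np.testing.assert_allclose(ms[:, 0, 0, 0], 1 / (1 + np.exp(-resp)),
                               atol=1e-6)


# ---------------------------------------------------------------------------
# gated fusion
# ---------------------------------------------------------------------------


def _gate_with_bias(bias, d=6):
    gf = GatedFusion(GateConfig(in_dim=2 * d, hidden=4, dropout=0.0)).eval()
    gf.fc2.weight.value[...] = 0
    gf.fc2.bias.value[...] = bias
    return gf


def test_gate_saturated_high_gives_elementwise_product(rng):
    fs = rng.standard_normal((3, 6)).astype(np.float32)
    fr = rng.standard_normal((3, 6)).astype(np.float32)
    gf = _gate_with_bias(50.0)
    np.testing.assert_allclose(gf(fs, fr), fs * fr, atol=1e-6)


def test_gate_saturated_low_gives_elementwise_sum(rng):
    fs = rng.standard_normal((3, 6)).astype(np.float32)
    fr = rng.standard_normal((3, 6)).astype(np.float32)
    gf = _gate_with_bias(-50.0)
    np.testing.assert_allclose(gf(fs, fr), fs + fr, atol=1e-6)


def test_gate_at_half_matches_closed_form(rng):
    v = rng.standard_normal((2, 6)).astype(np.float32)
    gf = _gate_with_bias(0.0)  # sigmoid(0) = 0.5
    np.testing.assert_allclose(gf(v, v), 0.5 * v * v + v, atol=1e-6)


def test_fused_output_bounded_between_pure_strategies(rng):
    gf = GatedFusion(GateConfig(in_dim=12, hidden=4, dropout=0.0)).eval()
    fs = rng.standard_normal((5, 6)).astype(np.float32)
    fr = rng.standard_normal((5, 6)).astype(np.float32)
    fused = gf(fs, fr)
    lo = np.minimum(fs * fr, fs + fr)
    hi = np.maximum(fs * fr, fs + fr)
    assert np.all(fused >= lo - 1e-6) and np.all(fused <= hi + 1e-6)


def test_gate_rejects_mismatched_inputs():
    gf = GatedFusion(GateConfig(in_dim=12, hidden=4))
    with pytest.raises(ValidationError):
        gf(np.zeros((1, 6)), np.zeros((1, 5)))


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_dualcm():
    nn.seed_all(0)
    spectral = build_spectral_net(SpectralNetConfig())
    spatial = build_spatial_net(SpatialNetConfig())
    return build_dualcmnet(spectral, spatial)


def test_dualcm_logits_shape_and_eval_determinism(small_dualcm, rng):
    model = small_dualcm.eval()
    spec = rng.random((3, 2151)).astype(np.float32)
    imgs = rng.random((3, 3, 64, 64)).astype(np.float32)
    logits = model(spec, imgs)
    assert logits.shape == (3, 11)
    np.testing.assert_array_equal(logits, model(spec, imgs))


def test_dualcm_parameter_budget_under_2_53M(small_dualcm):
    assert count_params(small_dualcm) <= 2_530_000


def test_dualcm_parameter_split_is_complete(small_dualcm):
    total = {id(p) for p in small_dualcm.parameters()}
    branch = {id(p) for p in small_dualcm.branch_parameters()}
    fusion = {id(p) for p in small_dualcm.fusion_parameters()}
    assert branch | fusion == total and not branch & fusion


def test_dualcm_backward_gradients_via_finite_differences(rng):
    """End-to-end gradient of the fusion stack (branches excluded) checked
    against central differences on a tiny assembly."""
    nn.seed_all(1)
    cfg = HShuffleConfig(in_dim=8, mid_dim=8, out_dim=8, groups=2)
    hs = HShuffleBlock(cfg)
    cbam = CBAM(CBAMConfig(channels=8, reduction=2, spatial_kernel=3))
    gate = GatedFusion(GateConfig(in_dim=16, hidden=4, dropout=0.0))
    head = nn.Linear(8, 3)

    class FusionStack(nn.Module):
        def __init__(self):
            super().__init__()
            self.hs, self.cbam, self.gate, self.head = hs, cbam, gate, head

        def forward(self, x):
            t = self.hs(x)
            a = self.cbam(t.reshape(-1, 8, 1, 1)).reshape(-1, 8)
            return self.head(self.gate(a, a))

        def backward(self, g):
            gfs, gfr = self.gate.backward(self.head.backward(g))
            ga = (gfs + gfr).reshape(-1, 8, 1, 1)
            return self.hs.backward(self.cbam.backward(ga).reshape(-1, 8))

    stack = to_float64(FusionStack()).eval()
    x = rng.standard_normal((3, 8))
    gradcheck(stack, x, lambda x_: stack(x_), stack.backward, tol=1e-5)
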