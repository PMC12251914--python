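"""Forward contracts and parameter arithmetic of the network blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yolo_ifsc import autodiff as ag
from yolo_ifsc import nn


def _t(arr):
    return ag.Tensor(np.asarray(arr, dtype=np.float32))


def _rand(shape, seed=0):
    return ag.Tensor(np.random.default_rng(seed).normal(0, 1, shape).astype(np.float32))


# ---------------------------------------------------------------------------
# CBS convolution unit
# ---------------------------------------------------------------------------

class TestCBS:
    def test_param_arithmetic_1x1(self):
        m = nn.Conv(16, 16, 1, 1)
        assert m.num_params() == 16 * 16 + 2 * 16 == 288

    def test_stride2_halves_spatial_size(self):
        m = nn.Conv(3, 8, 3, 2)
        y = m(_rand((1, 3, 64, 64)))
        assert y.shape == (1, 8, 32, 32)

    def test_zero_input_gives_constant_output(self):
        m = nn.Conv(4, 6, 3, 1).eval()
        y = m(_t(np.zeros((1, 4, 8, 8))))
        # activation of the normalisation shift, identical at every position
        assert np.allclose(y.data, y.data[:, :, :1, :1])

    def test_rejects_bad_hyperparameters(self):
        with pytest.raises(ValueError):
            nn.Conv(0, 4, 3)
        with pytest.raises(ValueError):
            nn.Conv(4, 4, 2)       # even kernel
        with pytest.raises(ValueError):
            nn.Conv(4, 4, 3, 0)    # stride < 1


# ---------------------------------------------------------------------------
# dynamic weight fusion
# ---------------------------------------------------------------------------

class TestDynamicFusion:
    def _paths(self, seed=0):
        r = np.random.default_rng(seed)
        return [_t(r.normal(0, 1, (1, 4, 5, 5))) for _ in range(5)]

    def test_zero_logits_give_arithmetic_mean(self):
        paths = self._paths()
        y = nn.dynamic_weight_fusion(_t(np.zeros(5)), paths)
        mean = np.mean([p.data for p in paths], axis=0)
        np.testing.assert_allclose(y.data, mean, atol=1e-6)

    def test_saturated_logit_selects_single_path(self):
        paths = self._paths()
        y = nn.dynamic_weight_fusion(_t([30.0, -30, -30, -30, -30]), paths)
        np.testing.assert_allclose(y.data, paths[0].data, atol=1e-6)

    def test_log_logits_reproduce_hand_computed_weights(self):
        # softmax(ln 1, ln 2, ln 3, ln 4, ln 0.5) = (1,2,3,4,0.5)/10.5,
        # verified by scalar brute force below
        logits = np.log([1.0, 2.0, 3.0, 4.0, 0.5]).astype(np.float32)
        brute = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(brute, np.array([1, 2, 3, 4, 0.5]) / 10.5,
                                   atol=1e-7)
        ones = [_t(np.ones((1, 2, 3, 3))) for _ in range(5)]
        scaled = [w * p for w, p in zip([1.0] * 5, ones)]
        y = nn.dynamic_weight_fusion(_t(logits), scaled)
        np.testing.assert_allclose(y.data, 1.0, atol=1e-6)  # weights sum to 1

    def test_shape_mismatch_is_an_error(self):
        paths = self._paths()
        paths[2] = _rand((1, 4, 4, 5))
        with pytest.raises(ValueError):
            nn.dynamic_weight_fusion(_t(np.zeros(5)), paths)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=5))
    def test_weights_sum_to_one_for_any_finite_logits(self, logits):
        w = _t(logits).softmax(axis=0).data
        assert abs(w.sum() - 1.0) < 1e-6
        assert np.all(w >= 0) and np.all(w <= 1)


# ---------------------------------------------------------------------------
# Inception-F
# ---------------------------------------------------------------------------

class TestInceptionF:
    @pytest.mark.parametrize("hw", [8, 20, 32, 80])
    def test_stride1_preserves_spatial_size(self, hw):
        m = nn.InceptionF(16, 16, "F", stride=1, pw_groups=4, r3_groups=4)
        y = m(_rand((1, 16, hw, hw)))
        assert y.shape == (1, 16, hw, hw)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            nn.InceptionF(8, 8, "Z")

    def test_variant_subset_consistency(self):
        """A and F agree up to the extra-path contributions when the shared
        paths carry identical parameters."""
        rng_a, rng_f = np.random.default_rng(5), np.random.default_rng(5)
        a = nn.InceptionF(8, 8, "A", pw_groups=2, r3_groups=2, rng=rng_a).eval()
        f = nn.InceptionF(8, 8, "F", pw_groups=2, r3_groups=2, rng=rng_f).eval()
        x = _rand((1, 8, 10, 10), seed=2)
        pa = [p.data for p in a.path_outputs(x)]
        pf = [p.data for p in f.path_outputs(x)]
        for shared_a, shared_f in zip(pa, pf[:3]):
            np.testing.assert_allclose(shared_a, shared_f, atol=1e-6)
        assert len(pf) == 5 and len(pa) == 3

    @pytest.mark.parametrize("c", [32, 64, 128])
    def test_variant_parameter_ordering(self, c):
        kw = dict(pw_groups=8, r3_groups=8)
        pa = nn.InceptionF(c, c, "A", **kw).num_params()
        pb = nn.InceptionF(c, c, "B", **kw).num_params()
        pf = nn.InceptionF(c, c, "F", **kw).num_params()
        assert pa <= pb <= pf


# ---------------------------------------------------------------------------
# PConv / C2f-Faster
# ---------------------------------------------------------------------------

class TestPConv:
    def test_untouched_channels_bit_identical(self):
        m = nn.PConv(64, 3, 0.25)
        x = _rand((2, 64, 9, 9))
        y = m(x)
        assert np.array_equal(y.data[:, 16:], x.data[:, 16:])

    def test_full_ratio_equals_standard_conv(self):
        m = nn.PConv(8, 3, 1.0)
        ref = nn.Conv2d(8, 8, 3, bias=False)
        ref.weight.data[...] = m.conv.weight.data
        x = _rand((1, 8, 7, 7))
        np.testing.assert_allclose(m(x).data, ref(x).data, atol=1e-6)

    def test_flop_ratio_is_exactly_the_partial_ratio(self):
        m = nn.PConv(64, 3, 0.25)
        full = nn.Conv2d(64, 64, 3, bias=False)
        assert m.macs(20, 20) * 4 == full.macs(20, 20)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            nn.PConv(8, 3, 0.0)
        with pytest.raises(ValueError):
            nn.PConv(8, 3, 1.5)


class TestFasterBottleneck:
    def test_shape_preserved(self):
        m = nn.FasterBottleneck(128)
        assert m(_rand((1, 128, 5, 5))).shape == (1, 128, 5, 5)

    def test_zero_projection_gives_residual_identity(self):
        m = nn.FasterBottleneck(16).eval()
        m.cv2.conv.weight.data[...] = 0.0
        m.cv2.bn.beta.data[...] = 0.0
        x = _rand((1, 16, 6, 6))
        np.testing.assert_allclose(m(x).data, x.data, atol=1e-6)

    def test_cheaper_than_standard_3x3_bottleneck(self):
        # brute-force enumeration of both blocks at width 128
        faster = nn.FasterBottleneck(128).num_params()
        standard = nn.Bottleneck(128, 128, k=(3, 3), e=1.0).num_params()
        assert faster < standard


class TestC2fFaster:
    def test_shape(self):
        m = nn.C2fFaster(256, 256, 1)
        assert m(_rand((1, 256, 8, 8))).shape == (1, 256, 8, 8)

    def test_hidden_concat_width(self):
        for n in (1, 2, 3):
            m = nn.C2fFaster(64, 64, n)
            assert m.cv2.conv.c1 == (2 + n) * (64 // 2)

    def test_requires_a_bottleneck(self):
        with pytest.raises(ValueError):
            nn.C2fFaster(8, 8, 0)


# ---------------------------------------------------------------------------
# pooling pyramids
# ---------------------------------------------------------------------------

class TestPoolingPyramids:
    def test_sppelanf_shapes(self):
        m = nn.SPPELANF(256, 256, c_star=128)
        x = _rand((1, 256, 20, 20))
        y0 = m.cv1(x)
        y1 = m.pool(y0)
        z = ag.concat([y0, m.f[0](y1), m.f[1](m.pool(y1)),
                       m.f[2](m.pool(m.pool(y1)))], axis=1)
        assert z.shape == (1, 512, 20, 20)           # 4 * c_star channels
        assert m(x).shape == (1, 256, 20, 20)

    def test_constant_input_makes_all_pool_stages_equal(self):
        m = nn.SPPELANF(8, 8, c_star=4).eval()
        y0 = m.cv1(_t(np.full((1, 8, 9, 9), 3.0)))
        y1, y2, y3 = m.pool(y0), m.pool(m.pool(y0)), m.pool(m.pool(m.pool(y0)))
        for y in (y1, y2, y3):
            np.testing.assert_allclose(y.data, y0.data, atol=1e-6)

    def test_sppf_constant_input_and_shape(self):
        m = nn.SPPF(256, 256).eval()
        x = _t(np.full((1, 256, 20, 20), 1.5))
        assert m(x).shape == (1, 256, 20, 20)
        y0 = m.cv1(x)
        np.testing.assert_allclose(m.pool(y0).data, y0.data, atol=1e-6)

    def test_sppelanf_rejects_degenerate_width(self):
        with pytest.raises(ValueError):
            nn.SPPELANF(1, 8)

    def test_sppelan_differs_by_the_three_fusion_convs(self):
        with_fpn = nn.SPPELANF(256, 256, c_star=16).num_params()
        without = nn.SPPELAN(256, 256, c_star=16).num_params()
        assert with_fpn - without == 3 * (16 * 16 + 2 * 16)


# ---------------------------------------------------------------------------
# CBAM attention
# ---------------------------------------------------------------------------

class TestCBAM:
    def test_zero_mlp_gives_half_gate(self):
        m = nn.ChannelAttention(8, 4)
        for p in m.parameters():
            p.data[...] = 0.0
        x = _rand((1, 8, 5, 5))
        mc = m.attention(x)
        np.testing.assert_allclose(mc.data, 0.5, atol=1e-7)
        np.testing.assert_allclose(m(x).data, x.data / 2, atol=1e-6)

    def test_spatially_constant_input_equalises_descriptors(self):
        m = nn.ChannelAttention(4, 2)
        x = _t(np.broadcast_to(np.arange(4, dtype=np.float32)[None, :, None, None],
                               (1, 4, 6, 6)).copy())
        avg = x.data.mean(axis=(2, 3))
        mx = x.data.max(axis=(2, 3))
        np.testing.assert_allclose(avg, mx)

    def test_zero_spatial_conv_gives_half_gate(self):
        m = nn.SpatialAttention()
        m.conv.weight.data[...] = 0.0
        m.conv.bias.data[...] = 0.0
        x = _rand((1, 6, 5, 5))
        np.testing.assert_allclose(m.attention(x).data, 0.5, atol=1e-7)

    def test_gates_lie_strictly_inside_unit_interval(self):
        m = nn.CBAM(8, 4)
        for trial in range(50):
            x = _rand((1, 8, 6, 6), seed=trial)
            mc = m.channel.attention(x).data
            ms = m.spatial.attention(x).data
            for gate in (mc, ms):
                assert np.all(gate > 0.0) and np.all(gate < 1.0)

    def test_output_magnitude_bounded_by_input(self):
        m = nn.CBAM(8, 4)
        for trial in range(10):
            x = _rand((2, 8, 7, 7), seed=100 + trial)
            y = m(x)
            assert np.all(np.abs(y.data) <= np.abs(x.data) + 1e-7)


# ---------------------------------------------------------------------------
# spatial-size preservation across stride-1 blocks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hw", [8, 20, 32, 80])
@pytest.mark.parametrize("factory", [
    lambda: nn.C3k2(16, 16), lambda: nn.SPPF(16, 16),
    lambda: nn.SPPELANF(16, 16, 8), lambda: nn.C2fFaster(16, 16),
    lambda: nn.CBAM(16, 4), lambda: nn.C2PSA(16, 16),
])
def test_stride1_blocks_preserve_spatial_dimensions(factory, hw):
    m = factory()
    assert m(_rand((1, 16, hw, hw))).shape == (1, 16, hw, hw)
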