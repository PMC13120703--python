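"""SpectralFlow: dynamic patch filters, smoothing, Eq-style conservation, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medspectralnet import Tensor, SpectralFlow, SpectralFlowConfig, smooth
from medspectralnet import autograd as ag


def make_module(channels=4, k=3, reduction=2, seed=0, **kw):
    cfg = SpectralFlowConfig(channels=channels, patch_size=k, reduction=reduction, **kw)
    return SpectralFlow(cfg, np.random.default_rng(seed)), cfg


def smooth_bruteforce(x, weights, k):
    """Independent per-patch loop oracle for the weighted patch means."""
    B, C, H, W = x.shape
    ph, pw = (-H) % k, (-W) % k
    mode = "reflect" if min(H, W) > 1 else "edge"
    xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode=mode)
    out = np.empty_like(xp)
    for b in range(B):
        for c in range(C):
            for i in range(0, H + ph, k):
                for j in range(0, W + pw, k):
                    patch = xp[b, c, i:i + k, j:j + k]
                    out[b, c, i:i + k, j:j + k] = (weights[b, c] * patch.ravel()).sum()
    return out[:, :, :H, :W]


class TestPatchFilterWeights:
    def test_zero_input_gives_uniform_weights(self):
        mod, cfg = make_module(channels=4, k=3)
        w = mod.patch_filter_weights(Tensor(np.zeros((2, 4, 5, 5), dtype=np.float32)))
        np.testing.assert_allclose(w.data, 1.0 / 9.0, atol=1e-7)

    def test_weights_normalized_over_patch_positions(self, rng):
        mod, _ = make_module(channels=6, k=3)
        w = mod.patch_filter_weights(Tensor(rng.standard_normal((3, 6, 7, 7)).astype(np.float32)))
        assert w.shape == (3, 3, 9)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)
        assert (w.data >= 0).all()

    def test_forced_logits_match_hand_softmax(self):
        # pre-softmax logits (0, ln2, ln2, 0) -> (1/6, 2/6, 2/6, 1/6)
        mod, _ = make_module(channels=2, k=2, reduction=2)
        mod.filter_gen.weight.data[:] = 0
        mod.filter_gen.bias.data[:] = np.log([1.0, 2.0, 2.0, 1.0])
        w = mod.patch_filter_weights(Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32)))
        np.testing.assert_allclose(w.data[0, 0], [1 / 6, 2 / 6, 2 / 6, 1 / 6], atol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        mod, _ = make_module(channels=4)
        with pytest.raises(ValueError, match="channels"):
            mod.patch_filter_weights(Tensor(rng.standard_normal((1, 3, 4, 4))))


class TestSmooth:
    def test_constant_input_stays_constant(self, rng):
        w = rng.dirichlet(np.ones(9), size=(1, 2)).astype(np.float32)
        x = np.full((1, 2, 7, 5), 3.25, dtype=np.float32)
        out = smooth(Tensor(x), Tensor(w), 3)
        np.testing.assert_allclose(out.data, 3.25, atol=1e-6)

    def test_uniform_weights_give_patch_means(self, rng):
        x = rng.standard_normal((1, 1, 6, 6)).astype(np.float64)
        w = np.full((1, 1, 9), 1 / 9)
        out = smooth(Tensor(x), Tensor(w), 3).data
        for i in range(0, 6, 3):
            for j in range(0, 6, 3):
                np.testing.assert_allclose(out[0, 0, i:i + 3, j:j + 3],
                                           x[0, 0, i:i + 3, j:j + 3].mean(), atol=1e-12)

    def test_k1_is_identity(self, rng):
        x = rng.standard_normal((2, 3, 4, 5))
        out = smooth(Tensor(x), Tensor(np.ones((2, 3, 1))), 1)
        np.testing.assert_array_equal(out.data, x)

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    @pytest.mark.parametrize("hw", [(6, 6), (7, 7)])
    def test_matches_bruteforce_patch_loop(self, k, hw, rng):
        H, W = hw
        x = rng.standard_normal((2, 3, H, W))
        w = rng.dirichlet(np.ones(k * k), size=(2, 3))
        out = smooth(Tensor(x), Tensor(w), k)
        np.testing.assert_allclose(out.data, smooth_bruteforce(x, w, k), atol=1e-10)
        assert out.shape == x.shape


class TestDecompose:
    def test_conservation_to_machine_precision(self, rng):
        # x_h is defined as x - x_la_proj, so reconstruction is exact in real
        # arithmetic; re-adding in float32 incurs at most one rounding step
        # scaled by the stream magnitude
        mod, _ = make_module(channels=6, seed=3)
        x = Tensor(rng.standard_normal((2, 6, 5, 5)).astype(np.float32))
        x_la = Tensor(rng.standard_normal((2, 3, 5, 5)).astype(np.float32))
        x_la_proj, x_h = mod.decompose(x, x_la)
        tol = 2 * np.finfo(np.float32).eps * max(
            np.abs(x_la_proj.data).max(), np.abs(x_h.data).max())
        np.testing.assert_allclose(x_la_proj.data + x_h.data, x.data, atol=tol, rtol=0)

    def test_zero_projection_leaves_input_as_residue(self, rng):
        mod, _ = make_module(channels=6)
        mod.proj.weight.data[:] = 0
        mod.proj.bias.data[:] = 0
        x = Tensor(rng.standard_normal((1, 6, 4, 4)).astype(np.float32))
        x_la_proj, x_h = mod.decompose(x, Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32)))
        np.testing.assert_array_equal(x_la_proj.data, 0)
        np.testing.assert_array_equal(x_h.data, x.data)


class TestStreamFuse:
    def test_zero_logits_give_half_half(self, rng):
        mod, _ = make_module(channels=4)
        mod.attn_low.weight.data[:] = 0
        mod.attn_high.weight.data[:] = 0
        low = Tensor(rng.standard_normal((2, 4, 3, 3)).astype(np.float32))
        high = Tensor(rng.standard_normal((2, 4, 3, 3)).astype(np.float32))
        _, a_l, a_h = mod.stream_fuse(low, high, return_attention=True)
        np.testing.assert_allclose(a_l.data, 0.5, atol=1e-7)
        np.testing.assert_allclose(a_h.data, 0.5, atol=1e-7)

    def test_zero_streams_give_zero_output(self):
        mod, _ = make_module(channels=4)
        z = Tensor(np.zeros((1, 4, 2, 2), dtype=np.float32))
        assert np.all(mod.stream_fuse(z, z).data == 0)

    def test_saturated_attention_selects_streams(self, rng):
        # a_l -> (1, 0), a_h -> (0, 1) with an identity final conv: channel 0
        # comes from the low stream, channel 1 from the high stream
        mod, _ = make_module(channels=2, reduction=2)
        mod.attn_low.weight.data[:] = 0
        mod.attn_high.weight.data[:] = 0
        mod.attn_low.bias.data[:] = [40.0, -40.0]
        mod.attn_high.bias.data[:] = [-40.0, 40.0]
        mod.fuse.weight.data[:] = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1)
        mod.fuse.bias.data[:] = 0
        low = Tensor(rng.standard_normal((1, 2, 1, 1)).astype(np.float32))
        high = Tensor(rng.standard_normal((1, 2, 1, 1)).astype(np.float32))
        out = mod.stream_fuse(low, high)
        np.testing.assert_allclose(out.data[0, 0], low.data[0, 0], atol=1e-6)
        np.testing.assert_allclose(out.data[0, 1], high.data[0, 1], atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        mod, _ = make_module(channels=4)
        with pytest.raises(ValueError):
            mod.stream_fuse(Tensor(np.zeros((1, 4, 2, 2))), Tensor(np.zeros((1, 4, 3, 2))))


class TestForward:
    @pytest.mark.parametrize("hw", [(7, 7), (1, 1), (5, 8)])
    def test_shape_preserved_even_when_k_does_not_divide(self, hw, rng):
        mod, _ = make_module(channels=4, k=3)
        x = Tensor(rng.standard_normal((2, 4, *hw)).astype(np.float32))
        assert mod(x).shape == x.shape

    def test_zero_input_zero_output_with_zero_bias(self):
        mod, _ = make_module(channels=4)
        out = mod(Tensor(np.zeros((1, 4, 6, 6), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0)

    def test_decomposition_invariants(self, rng):
        mod, _ = make_module(channels=8, k=3, seed=9)
        x = Tensor(rng.standard_normal((2, 8, 7, 7)).astype(np.float32))
        x_f, dec = mod(x, return_decomposition=True)
        np.testing.assert_allclose(dec.x_la_proj.data + dec.x_h.data, x.data, atol=1e-6)
        np.testing.assert_allclose(dec.patch_weights.data.sum(-1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(dec.a_l.data + dec.a_h.data, 1.0)
        assert 0 < dec.a_l.data.min() and dec.a_l.data.max() < 1
        assert dec.x_l.shape == (2, 4, 7, 7)
        assert dec.x_la_proj.shape == x.shape
        np.testing.assert_array_equal(x_f.data, dec.x_f.data)

    def test_sigmoid_stream_norm_bounds(self, rng):
        mod, _ = make_module(channels=4, stream_norm="sigmoid", seed=2)
        x = Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
        _, dec = mod(x, return_decomposition=True)
        for a in (dec.a_l.data, dec.a_h.data):
            assert ((0 < a) & (a < 1)).all()

    def test_deterministic(self, rng):
        mod, _ = make_module(channels=4, seed=5)
        x = Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32))
        np.testing.assert_array_equal(mod(x).data, mod(x).data)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(h=st.integers(1, 9), w=st.integers(1, 9), k=st.sampled_from([1, 2, 3, 5]),
       seed=st.integers(0, 3))
def test_conservation_and_shape_property(h, w, k, seed):
    """x_la_proj + x_h reconstructs the input for any extent and patch size."""
    r = np.random.default_rng(seed)
    cfg = SpectralFlowConfig(channels=4, patch_size=k, reduction=2)
    mod = SpectralFlow(cfg, r)
    x = Tensor(r.standard_normal((1, 4, h, w)).astype(np.float32))
    x_f, dec = mod(x, return_decomposition=True)
    assert x_f.shape == x.shape
    np.testing.assert_allclose(dec.x_la_proj.data + dec.x_h.data, x.data, atol=1e-5)


def test_config_validation():
    with pytest.raises(ValueError):
        SpectralFlowConfig(channels=5, reduction=2)
    with pytest.raises(ValueError):
        SpectralFlowConfig(channels=4, patch_size=0)
    with pytest.raises(ValueError):
        SpectralFlowConfig(channels=4, stream_norm="bogus")
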