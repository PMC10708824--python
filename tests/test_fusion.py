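import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import oracle_fuse
from conftest import random_pair
from nirfuse import (FusionParams, RegisteredPair, atmospheric_light,
                     complement, enhance, fuse, nir_term, transmission,
                     vegetation_index)


def make_pair(vis, nir):
    return RegisteredPair(vis=np.asarray(vis, float), nir=np.asarray(nir, float))


class TestVegetationIndex:
    def test_equal_bands_give_zero(self):
        pair = make_pair(np.full((2, 2, 3), 0.4), np.full((2, 2), 0.4))
        vm = vegetation_index(pair)
        assert np.allclose(vm.vi, 0.0)
        assert np.allclose(vm.vi_comp, 1.0)

    def test_range_extremes(self):
        vis = np.zeros((1, 2, 3))
        vis[0, 1, 0] = 0.8
        nir = np.array([[0.8, 0.0]])
        vm = vegetation_index(make_pair(vis, nir))
        assert vm.vi[0, 0] == pytest.approx(1.0)
        assert vm.vi[0, 1] == pytest.approx(-1.0)
        assert vm.vi_comp[0, 0] == pytest.approx(0.0)
        assert vm.vi_comp[0, 1] == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        vis = np.zeros((1, 1, 3))
        vis[0, 0, 0] = 0.2
        vm = vegetation_index(make_pair(vis, np.array([[0.6]])))
        assert vm.vi[0, 0] == pytest.approx(0.5)
        assert vm.vi_comp[0, 0] == pytest.approx(0.5)

    def test_zero_signal_guarded(self):
        vm = vegetation_index(make_pair(np.zeros((2, 2, 3)), np.zeros((2, 2))))
        assert np.allclose(vm.vi, 0.0)


class TestComplement:
    def test_endpoint_values_and_involution(self, rng):
        assert complement(np.array([0.0]))[0] == 1.0
        assert complement(np.array([1.0]))[0] == 0.0
        img = rng.random((4, 4, 3))
        assert np.allclose(complement(complement(img)), img)

    def test_eight_bit_arithmetic(self):
        assert complement(np.array([100 / 255]))[0] == pytest.approx(155 / 255)


class TestAtmosphericLight:
    def test_lowest_vi_white_pixel_gives_unit_light(self):
        vis = np.full((4, 4, 3), 0.3)
        nir = np.full((4, 4), 0.9)        # vegetation everywhere ...
        vis[2, 2] = 1.0
        nir[2, 2] = 0.3                   # ... except one white sky pixel
        pair = make_pair(vis, nir)
        light = atmospheric_light(pair, vegetation_index(pair))
        assert np.allclose(light, 1.0)

    def test_uniform_vi_ties_break_row_major(self):
        rng = np.random.default_rng(0)
        vis = rng.random((5, 5, 3))
        pair = make_pair(vis, vis[:, :, 0].copy())   # VI = 0 everywhere
        params = FusionParams(light_percentile=3 / 25.0)
        light = atmospheric_light(pair, vegetation_index(pair), params)
        expected = vis.reshape(-1, 3)[:3].max(axis=0)  # first 3 in scan order
        assert np.allclose(light, expected)

    def test_dark_sky_pixel_dominates_selection(self):
        vis = np.full((4, 4, 3), 0.9)
        nir = np.full((4, 4), 0.95)
        vis[1, 3] = [0.2, 0.25, 0.3]
        nir[1, 3] = 0.05                  # lowest VI, a dark sky pixel
        pair = make_pair(vis, nir)
        light = atmospheric_light(pair, vegetation_index(pair))
        assert np.allclose(light, [0.2, 0.25, 0.3])


class TestTransmission:
    def test_literal_form_scalar_values(self):
        img = np.full((1, 1, 3), 0.5)
        tmap = transmission(img, np.ones(3), FusionParams(omega=0.6))
        assert tmap.t[0, 0] == pytest.approx(0.2)

    def test_zero_dark_clamps_to_floor(self):
        tmap = transmission(np.zeros((2, 2, 3)), np.ones(3), FusionParams())
        assert np.allclose(tmap.t, 0.1)

    def test_dark_is_channel_minimum(self):
        img = np.array([[[0.2, 0.5, 0.8]]])
        tmap = transmission(img, np.ones(3), FusionParams(omega=0.0))
        assert tmap.dark[0, 0] == pytest.approx(0.2)
        assert tmap.t[0, 0] == pytest.approx(0.2)

    def test_canonical_form_available(self):
        img = np.full((1, 1, 3), 0.5)
        params = FusionParams(omega=0.6, transmission_form="canonical")
        tmap = transmission(img, np.ones(3), params)
        assert tmap.t[0, 0] == pytest.approx(1 - 0.6 * 0.5)


class TestEnhance:
    def test_atmospheric_light_is_fixed_point(self):
        light = np.array([0.8, 0.7, 0.6])
        comp = np.broadcast_to(light, (2, 2, 3)).copy()
        from nirfuse.fusion import TransmissionMap
        tmap = TransmissionMap(t=np.full((2, 2), 0.3),
                               dark=np.zeros((2, 2)), light=light)
        enhanced = enhance(comp, light, tmap)
        assert np.allclose(enhanced, 1.0 - light)

    def test_scalar_evaluation(self):
        from nirfuse.fusion import TransmissionMap
        light = np.full(3, 0.8)
        comp = np.full((1, 1, 3), 0.4)
        tmap = TransmissionMap(t=np.full((1, 1), 0.5),
                               dark=np.zeros((1, 1)), light=light)
        assert np.allclose(enhance(comp, light, tmap), 1.0)  # R=0 -> R'=1

    def test_unit_transmission_is_identity(self, rng):
        from nirfuse.fusion import TransmissionMap
        vis = rng.random((4, 4, 3))
        comp = complement(vis)
        light = np.full(3, 0.9)
        tmap = TransmissionMap(t=np.ones((4, 4)),
                               dark=np.zeros((4, 4)), light=light)
        assert np.allclose(enhance(comp, light, tmap), vis)


class TestNirTerm:
    def test_zero_affectation_gives_zero(self, rng):
        pair = random_pair(rng, 4, 4)
        fn = nir_term(pair, np.ones((4, 4)), FusionParams(delta=0.0))
        assert np.allclose(fn, 0.0)

    def test_gray_pixel_splits_evenly(self):
        pair = make_pair(np.full((1, 1, 3), 0.3), np.array([[0.6]]))
        fn = nir_term(pair, np.full((1, 1), 0.8), FusionParams(delta=0.5))
        assert np.allclose(fn, 0.5 * 0.6 * 0.8 / 3, atol=1e-6)

    def test_black_pixel_guarded_to_zero(self):
        pair = make_pair(np.zeros((1, 1, 3)), np.array([[0.9]]))
        fn = nir_term(pair, np.ones((1, 1)), FusionParams())
        assert np.allclose(fn, 0.0)


class TestFusePipeline:
    def test_identity_when_delta_zero_and_fully_vegetated(self):
        # vi = 1 everywhere -> vi_comp = 0 -> w = 0; delta = 0 -> FN = 0
        vis = np.zeros((4, 4, 3))
        vis[:, :, 1] = 0.5
        vis[:, :, 2] = 0.3
        pair = make_pair(vis, np.full((4, 4), 0.7))  # red = 0 -> VI = 1
        result = fuse(pair, FusionParams(delta=0.0))
        assert np.allclose(result.fused, vis)

    def test_full_weight_returns_pure_enhanced(self, rng):
        vis = rng.random((4, 4, 3))
        pair = make_pair(vis, np.zeros((4, 4)))      # VI <= 0 -> vi_comp = 1
        params = FusionParams(delta=0.0, omega=0.0, t_floor=1.0)  # t = 1
        result = fuse(pair, params)
        assert np.allclose(result.weights, 1.0)
        assert np.allclose(result.fused, result.enhanced)

    def test_matches_per_pixel_oracle_on_toy_pair(self, rng):
        vis = rng.random((4, 4, 3))
        nir = rng.random((4, 4))
        pair = make_pair(vis, nir)
        result = fuse(pair)
        ref = oracle_fuse(vis, nir)
        for key, got in [("vi", result.vmap.vi), ("light", result.tmap.light),
                         ("t", result.tmap.t), ("enhanced", result.enhanced),
                         ("fn", result.nir_term), ("weights", result.weights),
                         ("fused", result.fused)]:
            assert np.abs(got - ref[key]).max() < 1e-9, key


class TestInvariantsAndMonotonicity:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(arrays(np.float64, (3, 3, 3), elements=st.floats(0, 1)),
           arrays(np.float64, (3, 3), elements=st.floats(0, 1)),
           st.floats(0, 1), st.floats(0, 0.95))
    def test_output_always_in_unit_interval(self, vis, nir, delta, omega):
        result = fuse(make_pair(vis, nir),
                      FusionParams(delta=delta, omega=omega))
        assert result.fused.min() >= 0.0
        assert result.fused.max() <= 1.0
        assert result.weights.min() >= 0.0
        assert result.weights.max() <= 1.0

    def test_rgb_blend_is_convex_combination(self, rng):
        pair = random_pair(rng, 6, 6)
        result = fuse(pair)
        w = result.weights[:, :, None]
        blend = pair.vis * (1 - w) + result.enhanced * w
        lo = np.minimum(pair.vis, result.enhanced)
        hi = np.maximum(pair.vis, result.enhanced)
        assert np.all(blend >= lo - 1e-12)
        assert np.all(blend <= hi + 1e-12)

    def test_enhancement_amplitude_monotone_in_omega(self, rng):
        """|R - L| = |I' - L| / t is non-decreasing in omega."""
        vis = rng.random((5, 5, 3))
        nir = rng.random((5, 5))
        pair = make_pair(vis, nir)
        comp = complement(vis)
        vmap = vegetation_index(pair)
        prev = None
        for omega in (0.0, 0.2, 0.4, 0.6, 0.8):
            params = FusionParams(omega=omega)
            light = atmospheric_light(pair, vmap, params)
            tmap = transmission(comp, light, params)
            amplitude = np.abs(comp - light) / tmap.t[:, :, None]
            if prev is not None:
                assert np.all(amplitude >= prev - 1e-12)
            prev = amplitude

    def test_preclip_fused_monotone_in_delta(self, rng):
        pair = random_pair(rng, 5, 5)
        prev = None
        for delta in (0.0, 0.25, 0.5, 0.75, 1.0):
            result = fuse(pair, FusionParams(delta=delta))
            w = result.weights[:, :, None]
            preclip = (result.nir_term + pair.vis * (1 - w)
                       + result.enhanced * w)
            if prev is not None:
                assert np.all(preclip >= prev - 1e-12)
            prev = preclip


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"delta": 1.5}, {"omega": 1.0}, {"t_floor": 0.0},
        {"light_percentile": 0.0}, {"transmission_form": "weird"},
    ])
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FusionParams(**kwargs)
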