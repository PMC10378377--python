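"""Trace formation, mono-exponential fitting and high-b synthesis."""

import numpy as np
import pytest

from dwi_eip import (
    MagnitudeVolume,
    PhantomSpec,
    SynthesisConfig,
    fit_adc,
    make_phantom,
    synthesize_high_b,
    trace_weighted,
)
from dwi_eip.core import DiffusionVolumeMeta, ValidationError
from dwi_eip.trace_adc import TraceSet


def _vol(data, b, n_slices=1):
    meta = DiffusionVolumeMeta(
        b_value=b, direction_index=None, repetition_index=None, slice_thickness=3.0,
        in_plane_spacing=(1.75, 1.75), matrix_size=data.shape[1:], n_slices=n_slices,
    )
    return MagnitudeVolume(data=data, meta=meta, provenance="trace")


def _mono_exponential_traces(adc, s0=1000.0, bvals=(50.0, 500.0, 1000.0), shape=(1, 16, 16)):
    return TraceSet(volumes=[_vol(np.full(shape, s0 * np.exp(-b * adc)), b) for b in bvals])


class TestTrace:
    def test_single_direction_is_identity(self, rng):
        v = _vol(np.abs(rng.normal(size=(1, 16, 16))) + 1.0, 1000.0)
        out = trace_weighted([v])
        np.testing.assert_allclose(out.data, v.data)
        assert out.provenance == "trace"

    def test_geometric_mean_of_two_directions(self):
        a = _vol(np.full((1, 16, 16), 100.0), 1000.0)
        b = _vol(np.full((1, 16, 16), 400.0), 1000.0)
        np.testing.assert_allclose(trace_weighted([a, b]).data, 200.0)

    def test_identical_isotropic_directions_unchanged(self, rng):
        data = np.abs(rng.normal(size=(1, 16, 16))) + 1.0
        vols = [_vol(data.copy(), 1000.0) for _ in range(4)]
        np.testing.assert_allclose(trace_weighted(vols).data, data, rtol=1e-12)

    def test_mixed_b_values_rejected(self):
        with pytest.raises(ValidationError):
            trace_weighted([_vol(np.ones((1, 16, 16)), 500.0), _vol(np.ones((1, 16, 16)), 1000.0)])


class TestFit:
    def test_noiseless_fit_is_exact(self):
        traces = _mono_exponential_traces(adc=0.811e-3, s0=1000.0)
        adc_map, s0_map = fit_adc(traces)
        assert adc_map.fit_mask.all()
        np.testing.assert_allclose(adc_map.adc, 0.811e-3, rtol=1e-12)
        np.testing.assert_allclose(s0_map.s0, 1000.0, rtol=1e-12)

    @pytest.mark.parametrize("weights", ["uniform", "signal_squared"])
    def test_fit_exact_for_any_weighting(self, weights):
        traces = _mono_exponential_traces(adc=1.588e-3)
        adc_map, _ = fit_adc(traces, SynthesisConfig(fit_weights=weights))
        np.testing.assert_allclose(adc_map.adc, 1.588e-3, rtol=1e-12)

    def test_constant_signal_gives_zero_adc(self):
        traces = TraceSet(
            volumes=[_vol(np.full((1, 16, 16), 500.0), b) for b in (50.0, 500.0, 1000.0)]
        )
        adc_map, s0_map = fit_adc(traces)
        np.testing.assert_allclose(adc_map.adc, 0.0, atol=1e-15)
        np.testing.assert_allclose(s0_map.s0, 500.0, rtol=1e-12)

    def test_adc_clamped_to_physiological_ceiling(self):
        traces = _mono_exponential_traces(adc=6e-3)  # decays faster than the clamp
        adc_map, _ = fit_adc(traces, SynthesisConfig(adc_max=4e-3))
        assert adc_map.adc[adc_map.fit_mask].max() <= 4e-3

    def test_all_background_warns_and_masks_nothing(self):
        traces = TraceSet(
            volumes=[_vol(np.zeros((1, 16, 16)), b) for b in (50.0, 1000.0)]
        )
        with pytest.warns(UserWarning):
            adc_map, _ = fit_adc(traces)
        assert not adc_map.fit_mask.any()

    def test_two_bvalue_minimum_enforced(self):
        with pytest.raises(ValidationError):
            fit_adc(TraceSet(volumes=[_vol(np.ones((1, 16, 16)), 1000.0)]))


class TestSynthesis:
    def test_closed_form_extrapolation(self):
        traces = _mono_exponential_traces(adc=1.0e-3, s0=1000.0)
        config = SynthesisConfig(b_target=2000.0)
        adc_map, s0_map = fit_adc(traces, config)
        out = synthesize_high_b(adc_map, s0_map, config, max_acquired_b=1000.0)
        np.testing.assert_allclose(out.data, 1000.0 * np.exp(-2.0), rtol=1e-10)
        assert out.meta.b_value == 2000.0
        assert out.provenance == "synthesized"

    def test_zero_adc_returns_s0(self):
        traces = _mono_exponential_traces(adc=1e-12, s0=750.0)
        config = SynthesisConfig()
        adc_map, s0_map = fit_adc(traces, config)
        out = synthesize_high_b(adc_map, s0_map, config, max_acquired_b=1000.0)
        np.testing.assert_allclose(out.data, 750.0, rtol=1e-6)

    def test_b_target_below_acquired_rejected(self):
        traces = _mono_exponential_traces(adc=1e-3)
        config = SynthesisConfig(b_target=800.0)
        adc_map, s0_map = fit_adc(traces, config)
        with pytest.raises(ValidationError):
            synthesize_high_b(adc_map, s0_map, config, max_acquired_b=1000.0)

    def test_noiseless_phantom_synthesis_matches_forward_model(self):
        spec = PhantomSpec(n_slices=1)
        truth = make_phantom(spec)
        traces = TraceSet(
            volumes=[truth.noiseless_magnitude(b) for b in (50.0, 500.0, 1000.0)]
        )
        config = SynthesisConfig(b_target=2000.0)
        adc_map, s0_map = fit_adc(traces, config)
        out = synthesize_high_b(adc_map, s0_map, config, max_acquired_b=1000.0)
        expected = truth.s0_true * np.exp(-2000.0 * truth.adc_true)
        tissue = truth.s0_true > 0
        rel = np.abs(out.data[tissue] - expected[tissue]) / expected[tissue]
        assert rel.max() < 1e-6
        np.testing.assert_array_equal(out.data[~tissue], 0.0)

    def test_synthesized_signal_decreases_with_b_target(self):
        traces = _mono_exponential_traces(adc=1.2e-3)
        values = []
        for b_target in (1500.0, 2000.0, 3000.0):
            config = SynthesisConfig(b_target=b_target)
            adc_map, s0_map = fit_adc(traces, config)
            values.append(
                synthesize_high_b(adc_map, s0_map, config, max_acquired_b=1000.0).data.mean()
            )
        assert values[0] > values[1] > values[2]

    def test_contrast_amplification_matches_closed_form(self):
        """Equal S0, lesion ADC < normal ADC: the lesion/normal ratio at
        b=2000 exceeds that at b=1000 by exactly exp(1000*(adc_n - adc_l))."""
        adc_l, adc_n = 0.811e-3, 1.588e-3
        s = {}
        for name, adc in (("lesion", adc_l), ("normal", adc_n)):
            traces = _mono_exponential_traces(adc=adc)
            config = SynthesisConfig(b_target=2000.0)
            adc_map, s0_map = fit_adc(traces, config)
            s[name] = {
                1000.0: traces.volumes[-1].data.mean(),
                2000.0: synthesize_high_b(adc_map, s0_map, config, 1000.0).data.mean(),
            }
        amplification = (s["lesion"][2000.0] / s["normal"][2000.0]) / (
            s["lesion"][1000.0] / s["normal"][1000.0]
        )
        np.testing.assert_allclose(amplification, np.exp(1000.0 * (adc_n - adc_l)), rtol=1e-9)
        np.testing.assert_allclose(amplification, 2.175, atol=2e-3)
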