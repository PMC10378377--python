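"""Patch phase estimation and SVD-based complex combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwi_eip import (
    PhantomSpec,
    apply_phase_correction,
    combine_patch_stack,
    complex_average_volume,
    estimate_linear_phase,
    magnitude_average_volume,
    make_phantom,
    simulate_stacks,
)
from dwi_eip.combine import _combine_slice
from dwi_eip.core import ComplexRepetitionStack, DiffusionVolumeMeta


def _ramp_patch(p_row, p_col, k=5, amplitude=None):
    y0, y1 = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    amp = amplitude if amplitude is not None else np.ones((k, k))
    return amp * np.exp(1j * (p_row * y0 + p_col * y1))


def _meta(n_slices=1, b=1000.0):
    return DiffusionVolumeMeta(
        b_value=b, direction_index=0, repetition_index=None, slice_thickness=3.0,
        in_plane_spacing=(1.75, 1.75), matrix_size=(114, 114), n_slices=n_slices,
    )


class TestPhaseEstimation:
    def test_constant_patch_has_zero_ramp(self):
        ramp = estimate_linear_phase(np.full((5, 5), 3.0, dtype=complex))
        assert ramp.p == (0.0, 0.0)
        assert not ramp.degenerate

    def test_all_zero_patch_flagged_degenerate(self):
        ramp = estimate_linear_phase(np.zeros((5, 5), dtype=complex))
        assert ramp.p == (0.0, 0.0)
        assert ramp.degenerate

    def test_pure_ramp_recovered_exactly(self):
        ramp = estimate_linear_phase(_ramp_patch(0.3, -0.1))
        np.testing.assert_allclose(ramp.p, (0.3, -0.1), atol=1e-12)

    @given(
        p_row=st.floats(-2.5, 2.5),
        p_col=st.floats(-2.5, 2.5),
        phi=st.floats(-np.pi, np.pi),
    )
    @settings(max_examples=50, deadline=None)
    def test_ramp_recovery_and_global_phase_invariance(self, p_row, p_col, phi):
        """Any pure ramp (with nonuniform positive amplitude) is recovered
        exactly; a global phase factor never changes the estimate."""
        rng = np.random.default_rng(42)
        amp = 0.5 + rng.random((5, 5))
        patch = _ramp_patch(p_row, p_col, amplitude=amp)
        ramp = estimate_linear_phase(patch)
        np.testing.assert_allclose(ramp.p, (p_row, p_col), atol=1e-10)
        ramp_shifted = estimate_linear_phase(patch * np.exp(1j * phi))
        np.testing.assert_allclose(ramp_shifted.p, ramp.p, atol=1e-10)

    def test_correction_cancels_own_ramp(self):
        patch = _ramp_patch(0.27, -0.31)
        corrected = apply_phase_correction(patch, estimate_linear_phase(patch))
        phases = np.angle(corrected * np.conj(corrected[2, 2]) / np.abs(corrected[2, 2]))
        assert np.ptp(phases) < 1e-10

    def test_zero_ramp_correction_is_identity(self):
        patch = _ramp_patch(0.2, 0.1)
        out = apply_phase_correction(patch, estimate_linear_phase(np.ones((5, 5)) + 0j))
        np.testing.assert_array_equal(out, patch)

    def test_correction_is_invertible(self):
        from dwi_eip.combine import PhaseRamp

        patch = _ramp_patch(0.2, 0.1) * (1 + np.arange(25).reshape(5, 5))
        ramp = PhaseRamp((0.4, -0.2))
        inverse = PhaseRamp((-0.4, 0.2))
        back = apply_phase_correction(apply_phase_correction(patch, ramp), inverse)
        np.testing.assert_allclose(back, patch, atol=1e-12)

    def test_center_pixel_untouched_by_correction(self):
        from dwi_eip.combine import PhaseRamp

        patch = _ramp_patch(0.2, 0.1)
        out = apply_phase_correction(patch, PhaseRamp((1.0, -1.0)))
        assert out[2, 2] == patch[2, 2]


class TestPatchCombination:
    def test_identical_repetitions_return_center_value(self, rng):
        t = rng.normal(size=25) + 1j * rng.normal(size=25)
        for n_rep in (1, 2, 9):
            out = combine_patch_stack(np.tile(t, (n_rep, 1)))
            np.testing.assert_allclose(out, t[12], rtol=1e-10)

    def test_empty_stack_rejected(self):
        with pytest.raises(Exception):
            combine_patch_stack(np.empty((0, 25), dtype=complex))

    def test_all_zero_stack_combines_to_zero(self):
        assert combine_patch_stack(np.zeros((9, 25), dtype=complex)) == 0

    def test_power_iteration_matches_dense_svd(self, rng):
        errs = []
        for _ in range(100):
            m = rng.normal(size=(9, 25)) + 1j * rng.normal(size=(9, 25))
            a = combine_patch_stack(m, method="power_iteration")
            b = combine_patch_stack(m, method="full_svd")
            errs.append(abs(a - b) / abs(b))
        assert max(errs) < 1e-8


class TestVolumeCombination:
    def test_noiseless_ramped_stack_recovers_truth(self, noiseless_ramp_stacks):
        truth, stacks = noiseless_ramp_stacks
        stack = next(s for s in stacks if s.meta.b_value == 1000.0)
        out = complex_average_volume(stack)
        expected = truth.s0_true * np.exp(-1000.0 * truth.adc_true)
        interior = np.zeros(expected.shape, dtype=bool)
        interior[:, 3:-3, 3:-3] = True
        m = interior & (expected > 0)
        rel = np.abs(out.data[m] - expected[m]) / expected[m]
        assert rel.max() < 1e-6
        assert out.provenance == "complex_average"

    def test_single_repetition_zero_phase_returns_magnitude(self, rng):
        img = rng.normal(size=(1, 1, 114, 114)) + 0j
        stack = ComplexRepetitionStack(data=img, meta=_meta())
        out = complex_average_volume(stack)
        np.testing.assert_allclose(out.data, np.abs(img[0]), rtol=1e-9)

    def test_magnitude_average_identities(self, rng):
        img = rng.normal(size=(3, 1, 114, 114)) + 1j * rng.normal(size=(3, 1, 114, 114))
        stack = ComplexRepetitionStack(data=img, meta=_meta())
        out = magnitude_average_volume(stack)
        np.testing.assert_allclose(out.data, np.abs(img).mean(axis=0))
        single = magnitude_average_volume(
            ComplexRepetitionStack(data=img[:1], meta=_meta())
        )
        np.testing.assert_allclose(single.data, np.abs(img[0]))

    def test_global_per_repetition_phase_invariance(self, rng):
        img = rng.normal(size=(4, 1, 64, 64)) + 1j * rng.normal(size=(4, 1, 64, 64))
        meta = DiffusionVolumeMeta(
            b_value=1000.0, direction_index=0, repetition_index=None, slice_thickness=3.0,
            in_plane_spacing=(1.75, 1.75), matrix_size=(64, 64), n_slices=1,
        )
        base = complex_average_volume(ComplexRepetitionStack(data=img, meta=meta))
        phases = np.exp(1j * rng.uniform(-np.pi, np.pi, size=4))
        shifted = complex_average_volume(
            ComplexRepetitionStack(data=img * phases[:, None, None, None], meta=meta)
        )
        np.testing.assert_allclose(shifted.data, base.data, atol=1e-10 * np.abs(base.data).max())

    def test_scale_equivariance(self, rng):
        img = rng.normal(size=(3, 1, 64, 64)) + 1j * rng.normal(size=(3, 1, 64, 64))
        meta = DiffusionVolumeMeta(
            b_value=1000.0, direction_index=0, repetition_index=None, slice_thickness=3.0,
            in_plane_spacing=(1.75, 1.75), matrix_size=(64, 64), n_slices=1,
        )
        base = complex_average_volume(ComplexRepetitionStack(data=img, meta=meta))
        scaled = complex_average_volume(ComplexRepetitionStack(data=3.5 * img, meta=meta))
        np.testing.assert_allclose(scaled.data, 3.5 * base.data, rtol=1e-9)
        mag_base = magnitude_average_volume(ComplexRepetitionStack(data=img, meta=meta))
        mag_scaled = magnitude_average_volume(ComplexRepetitionStack(data=3.5 * img, meta=meta))
        np.testing.assert_allclose(mag_scaled.data, 3.5 * mag_base.data, rtol=1e-12)

    def test_jit_kernel_matches_numpy_reference(self):
        """The compiled sliding-window kernel and the vectorized numpy
        implementation are two routes to the same algorithm."""
        spec = PhantomSpec(n_slices=1, seed=21)
        truth = make_phantom(spec)
        stack = next(
            s for s in simulate_stacks(truth, spec) if s.meta.b_value == 1000.0
        )
        fast = complex_average_volume(stack)
        ref = np.abs(_combine_slice(stack.data[:, 0], 5))
        np.testing.assert_allclose(fast.data[0], ref, rtol=1e-7, atol=1e-9)

    def test_noise_bias_ordering_on_background(self):
        """Complex combination suppresses the Rayleigh background floor that
        magnitude averaging retains."""
        sigma = 50.0
        meta = _meta()
        rng = np.random.default_rng(5)
        noise = rng.normal(scale=sigma, size=(9, 1, 114, 114, 2))
        stack = ComplexRepetitionStack(data=noise[..., 0] + 1j * noise[..., 1], meta=meta)
        mag = magnitude_average_volume(stack).data.mean()
        cplx = complex_average_volume(stack).data.mean()
        rayleigh = sigma * np.sqrt(np.pi / 2)
        assert np.isclose(mag, rayleigh, rtol=0.02)
        assert cplx <= 0.6 * rayleigh
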