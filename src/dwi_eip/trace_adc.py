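"""Trace-weighted images, mono-exponential ADC fitting and computed
high-b-value synthesis.

The trace-weighted image at a b-value is the geometric mean of the
per-direction images — equivalently the exponential of the mean
log-signal, which is the rotation-invariant combination implied by the
mono-exponential model ``S_d(b) = S0·exp(-b·ADC_d)``.

ADC and S0 come from a per-voxel weighted least-squares fit of
``ln S(b) = ln S0 - b·ADC`` over all acquired b-values; with
``signal_squared`` weights the log-domain fit approximates native-domain
least squares.  Computed high-b-value images are the noise-suppressed
extrapolation ``S(b_t) = S0·exp(-b_t·ADC)``: ADC is clamped to a
physiological range and voxels below a background threshold (a multiple
of the estimated noise level) are excluded from the fit and set to zero,
which removes the amplified-background appearance that direct
extrapolation of noisy voxels would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np

from dwi_eip.core import ADCMap, MagnitudeVolume, S0Map, ValidationError

__all__ = ["TraceSet", "SynthesisConfig", "trace_weighted", "fit_adc", "synthesize_high_b"]


@dataclass
class TraceSet:
    """Trace-weighted volumes at strictly increasing b-values."""

    volumes: list[MagnitudeVolume]

    def __post_init__(self) -> None:
        if len(self.volumes) < 1:
            raise ValidationError("TraceSet needs >= 1 volume")
        bvals = self.b_values
        if any(b2 <= b1 for b1, b2 in zip(bvals, bvals[1:])):
            raise ValidationError("b-values must be strictly increasing")
        shapes = {v.data.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValidationError("trace volumes must share one grid")

    @property
    def b_values(self) -> list[float]:
        return [v.meta.b_value for v in self.volumes]


@dataclass(frozen=True)
class SynthesisConfig:
    """Controls for fitting and extrapolation.

    ``b_target``: synthesis b-value in s/mm² (must exceed the largest
    acquired b).  ``adc_max``: clamp ceiling in mm²/s.
    ``background_threshold_factor``: voxels whose highest-b trace signal is
    below this multiple of the estimated noise level are treated as
    background.  ``fit_weights``: ``"signal_squared"`` or ``"uniform"``.
    """

    b_target: float = 2000.0
    adc_max: float = 4.0e-3
    background_threshold_factor: float = 2.0
    fit_weights: str = "signal_squared"

    def __post_init__(self) -> None:
        if self.adc_max <= 0:
            raise ValidationError("adc_max must be > 0")
        if self.fit_weights not in ("uniform", "signal_squared"):
            raise ValidationError(f"unknown fit_weights {self.fit_weights!r}")


def trace_weighted(direction_volumes: list[MagnitudeVolume]) -> MagnitudeVolume:
    """Voxel-wise geometric mean across diffusion directions (same b)."""
    if len(direction_volumes) < 1:
        raise ValidationError("need >= 1 direction volume")
    bvals = {v.meta.b_value for v in direction_volumes}
    if len(bvals) != 1:
        raise ValidationError(f"mixed b-values {sorted(bvals)} in trace formation")
    stack = np.stack([v.data for v in direction_volumes])
    # geometric mean via log; zero anywhere -> zero (product of signals)
    with np.errstate(divide="ignore"):
        logs = np.log(stack)
    out = np.exp(np.mean(logs, axis=0))
    out[np.any(stack == 0, axis=0)] = 0.0
    meta = direction_volumes[0].meta
    meta = replace(meta, direction_index=None, repetition_index=None)
    return MagnitudeVolume(data=out, meta=meta, provenance="trace")


def estimate_noise_level(volume: MagnitudeVolume, margin: int = 4) -> float:
    """Noise level σ estimated from the image border.

    The outermost ``margin`` pixels of every slice are assumed signal-free;
    their magnitude is then Rayleigh distributed with standard deviation
    σ·√((4−π)/2), inverted here to estimate σ.  Using the spread rather
    than the level makes the estimate vanish on noise-free data even when
    the border holds a constant offset.
    """
    data = volume.data
    border = np.ones(data.shape[1:], dtype=bool)
    border[margin:-margin, margin:-margin] = False
    vals = data[:, border]
    return float(np.std(vals) / np.sqrt((4.0 - np.pi) / 2.0))


def fit_adc(traces: TraceSet, config: SynthesisConfig = SynthesisConfig()) -> tuple[ADCMap, S0Map]:
    """Per-voxel weighted least-squares mono-exponential fit.

    Fits ``ln S(b) = ln S0 - b·ADC`` over all acquired b-values.  Voxels
    whose highest-b signal falls below
    ``background_threshold_factor × σ̂`` (σ̂ from
    :func:`estimate_noise_level`), or with nonpositive signal at any b,
    get ``fit_mask = False`` and ``adc = s0 = 0``.  ADC is clamped to
    ``[0, adc_max]``.  Exact on noiseless mono-exponential input.
    """
    if len(traces.volumes) < 2:
        raise ValidationError("ADC fit needs >= 2 b-values")
    b = np.asarray(traces.b_values)
    signal = np.stack([v.data for v in traces.volumes])  # (B, S, H, W)

    high_b = traces.volumes[-1]
    sigma = estimate_noise_level(high_b)
    threshold = config.background_threshold_factor * sigma
    mask = (high_b.data > threshold) & np.all(signal > 0, axis=0)
    if not mask.any():
        warnings.warn("ADC fit: no voxels above background threshold", stacklevel=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_s = np.where(signal > 0, np.log(np.maximum(signal, 1e-300)), 0.0)
    if config.fit_weights == "signal_squared":
        w = signal**2
    else:
        w = np.ones_like(signal)

    bb = b[:, None, None, None]
    sw = np.sum(w, axis=0)
    sb = np.sum(w * bb, axis=0)
    sbb = np.sum(w * bb**2, axis=0)
    sy = np.sum(w * log_s, axis=0)
    sby = np.sum(w * bb * log_s, axis=0)
    denom = sw * sbb - sb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * sby - sb * sy) / denom
        intercept = (sy - slope * sb) / sw
    adc = np.where(mask & (denom > 0), -slope, 0.0)
    adc = np.clip(adc, 0.0, config.adc_max)
    s0 = np.where(mask & (denom > 0), np.exp(intercept), 0.0)
    mask = mask & (denom > 0)

    meta = traces.volumes[0].meta
    meta = replace(meta, b_value=0.0)
    return (
        ADCMap(adc=adc, fit_mask=mask, meta=meta, adc_max=config.adc_max),
        S0Map(s0=s0, fit_mask=mask, meta=meta),
    )


def synthesize_high_b(
    adc: ADCMap, s0: S0Map, config: SynthesisConfig, max_acquired_b: float
) -> MagnitudeVolume:
    """Compute a high-b-value image ``S0·exp(-b_target·ADC)`` on the fit
    mask, zero elsewhere.  ``b_target`` must exceed the largest acquired b."""
    if config.b_target <= max_acquired_b:
        raise ValidationError(
            f"b_target {config.b_target} must exceed max acquired b {max_acquired_b}"
        )
    data = np.where(adc.fit_mask, s0.s0 * np.exp(-config.b_target * adc.adc), 0.0)
    meta = replace(adc.meta, b_value=config.b_target)
    return MagnitudeVolume(data=data, meta=meta, provenance="synthesized")
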