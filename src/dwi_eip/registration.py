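"""Non-rigid in-plane alignment of DWI volumes.

Two alignment passes are needed in the reconstruction chain: repetitions
of one diffusion weighting are aligned before complex combination, and
trace-weighted images of different b-values are aligned before ADC
fitting.  Both use the same demons-style displacement estimation driven by
magnitude images: a sum-of-squared-differences force with Gaussian field
smoothing, run in a 3-level multi-resolution scheme per slice
(through-plane motion is not modelled; prostate DWI slices are thick
relative to in-plane resolution and the emulated motion is in-plane).

Displacement fields are stored as ``(2, slice, row, col)`` arrays in mm,
components ordered (row, col); ``moving(x + u(x)) ≈ fixed(x)``.  Fields
estimated on magnitudes are applied identically to the real and imaginary
channels so phase travels with its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from dwi_eip.core import ComplexRepetitionStack, MagnitudeVolume, ValidationError

__all__ = [
    "RegistrationParams",
    "register_pair",
    "warp",
    "align_repetitions",
    "align_across_bvalues",
]


@dataclass(frozen=True)
class RegistrationParams:
    """Demons controls: iterations per level, Gaussian field smoothing (in
    voxels), shrink factors of the multi-resolution pyramid, and a hard
    cap on displacement magnitude (mm)."""

    iterations_per_level: int = 50
    smoothing_sigma_voxels: float = 2.0
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    max_displacement_mm: float = 10.0


def _demons_slice(
    fixed: np.ndarray, moving: np.ndarray, spacing: tuple[float, float], params: RegistrationParams
) -> np.ndarray:
    """2-D demons displacement field (2, H, W) in mm, (row, col) components."""
    if params.iterations_per_level == 0:
        return np.zeros((2,) + fixed.shape)
    # sitk 2-D images index (x=col, y=row); spacing likewise
    f_img = sitk.GetImageFromArray(fixed.astype(np.float64))
    m_img = sitk.GetImageFromArray(moving.astype(np.float64))
    for img in (f_img, m_img):
        img.SetSpacing((spacing[1], spacing[0]))

    demons = sitk.DemonsRegistrationFilter()
    demons.SetNumberOfIterations(params.iterations_per_level)
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(params.smoothing_sigma_voxels * min(spacing))

    field: sitk.Image | None = None
    for shrink in params.shrink_factors:
        f_lvl = sitk.Shrink(f_img, [shrink, shrink]) if shrink > 1 else f_img
        m_lvl = sitk.Shrink(m_img, [shrink, shrink]) if shrink > 1 else m_img
        if field is None:
            field = sitk.Image(f_lvl.GetSize(), sitk.sitkVectorFloat64, 2)
            field.CopyInformation(f_lvl)
        else:
            field = sitk.Resample(field, f_lvl, sitk.Transform(), sitk.sitkLinear)
        field = demons.Execute(f_lvl, m_lvl, field)
    arr = sitk.GetArrayFromImage(field)  # (H, W, 2) with (x, y) = (col, row) in mm
    out = np.stack([arr[..., 1], arr[..., 0]])
    cap = params.max_displacement_mm
    mag = np.sqrt(out[0] ** 2 + out[1] ** 2)
    scale = np.where(mag > cap, cap / np.maximum(mag, 1e-12), 1.0)
    return out * scale


def register_pair(
    moving: MagnitudeVolume, fixed: MagnitudeVolume, params: RegistrationParams = RegistrationParams()
) -> np.ndarray:
    """Estimate the per-slice displacement field mapping ``fixed`` voxel
    positions into ``moving`` so that ``warp(moving, field) ≈ fixed``.

    Returns a ``(2, slice, row, col)`` array in mm.  Deterministic given
    inputs and params; ``iterations_per_level = 0`` returns a zero field.
    """
    if moving.data.shape != fixed.data.shape:
        raise ValidationError("register_pair requires identical grids")
    spacing = fixed.meta.in_plane_spacing
    fields = [
        _demons_slice(fixed.data[s], moving.data[s], spacing, params)
        for s in range(fixed.data.shape[0])
    ]
    return np.stack(fields, axis=1)


def _warp_array(data: np.ndarray, field_mm: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    out = np.empty_like(data, dtype=np.float64)
    n_rows, n_cols = data.shape[1:]
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    for s in range(data.shape[0]):
        coords = [
            rows + field_mm[0, s] / spacing[0],
            cols + field_mm[1, s] / spacing[1],
        ]
        out[s] = map_coordinates(data[s], coords, order=1, mode="nearest")
    return out


def warp(volume: MagnitudeVolume, field_mm: np.ndarray) -> MagnitudeVolume:
    """Resample a volume through a displacement field (linear interpolation,
    border values extended outside the grid)."""
    if field_mm.shape != (2,) + volume.data.shape:
        raise ValidationError("field grid does not match volume")
    data = _warp_array(volume.data, field_mm, volume.meta.in_plane_spacing)
    return MagnitudeVolume(data=np.maximum(data, 0.0), meta=volume.meta, provenance=volume.provenance)


def align_repetitions(
    stack: ComplexRepetitionStack,
    reference: str = "first",
    params: RegistrationParams = RegistrationParams(),
) -> ComplexRepetitionStack:
    """Align all repetitions of a stack to a common reference.

    Fields are estimated on repetition magnitudes against the reference
    (``"first"`` repetition or the voxel-wise ``"mean"`` magnitude) and
    applied to the real and imaginary channels identically.  A single
    repetition is returned unchanged.
    """
    if reference not in ("first", "mean"):
        raise ValidationError("reference must be 'first' or 'mean'")
    if stack.n_repetitions < 2:
        return stack
    mags = np.abs(stack.data)
    ref = mags[0] if reference == "first" else mags.mean(axis=0)
    spacing = stack.meta.in_plane_spacing
    out = np.empty_like(stack.data)
    for r in range(stack.n_repetitions):
        if reference == "first" and r == 0:
            out[r] = stack.data[r]
            continue
        fields = [
            _demons_slice(ref[s], mags[r, s], spacing, params) for s in range(mags.shape[1])
        ]
        field = np.stack(fields, axis=1)
        out[r] = _warp_array(stack.data[r].real, field, spacing) + 1j * _warp_array(
            stack.data[r].imag, field, spacing
        )
    return ComplexRepetitionStack(data=out, meta=stack.meta)


def align_across_bvalues(
    traces: list[MagnitudeVolume], params: RegistrationParams = RegistrationParams()
) -> list[MagnitudeVolume]:
    """Register all trace volumes to the lowest-b trace (highest SNR)."""
    bvals = [v.meta.b_value for v in traces]
    if any(b2 <= b1 for b1, b2 in zip(bvals, bvals[1:])):
        raise ValidationError("b-values must be strictly increasing")
    if len(traces) < 2:
        return list(traces)
    ref = traces[0]
    out = [ref]
    ref_level = float(np.median(ref.data[ref.data > 0])) if (ref.data > 0).any() else 1.0
    for vol in traces[1:]:
        # demons is SSD-driven: bring the moving image to the reference's
        # intensity level before estimating the field, then warp the original
        level = float(np.median(vol.data[vol.data > 0])) if (vol.data > 0).any() else 1.0
        scaled = MagnitudeVolume(
            data=vol.data * (ref_level / level), meta=vol.meta, provenance=vol.provenance
        )
        field = register_pair(scaled, ref, params)
        out.append(warp(vol, field))
    return out
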