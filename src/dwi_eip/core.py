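"""Shared data types, grid conventions and volume/metadata I/O.

Conventions used throughout the package:

* voxel indices are 0-based and ordered ``(slice, row, col)``;
* ranges are half-open;
* the apparent diffusion coefficient (ADC) is carried internally in
  mm²/s and only converted to the conventional reporting unit of
  10⁻⁶ mm²/s at I/O boundaries (CSV reports);
* real-valued volumes are stored as NIfTI-1 files with a JSON sidecar,
  complex stacks as paired ``*_real.nii.gz`` / ``*_imag.nii.gz`` volumes
  plus a sidecar, because NIfTI has no portable complex dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DiffusionVolumeMeta",
    "ComplexRepetitionStack",
    "MagnitudeVolume",
    "ADCMap",
    "S0Map",
    "ROISet",
    "read_complex_stack",
    "write_complex_stack",
    "read_magnitude_volume",
    "write_magnitude_volume",
]

#: allowed provenance tags for magnitude volumes
PROVENANCES = (
    "magnitude_average",
    "complex_average",
    "trace",
    "synthesized",
    "phantom_truth",
)


class FormatError(RuntimeError):
    """Raised when an on-disk artifact is structurally invalid (e.g. a
    missing sidecar or mismatched real/imaginary pair)."""


class ValidationError(ValueError):
    """Raised when data violate a declared invariant (negative b-value,
    non-finite voxels, grid mismatch, ...)."""


@dataclass(frozen=True)
class DiffusionVolumeMeta:
    """Per-volume acquisition metadata.

    Parameters
    ----------
    b_value:
        Diffusion weighting in s/mm²; must be nonnegative.
    direction_index:
        Diffusion-direction index in ``0..D-1``; ``None`` for volumes that
        are already direction-combined (trace images, ADC maps).
    repetition_index:
        Repetition (average) index; ``None`` for combined volumes.
    slice_thickness:
        Through-plane voxel size in mm.
    in_plane_spacing:
        ``(row, col)`` pixel size in mm.
    matrix_size:
        ``(rows, cols)``.
    n_slices:
        Number of slices in the stack.
    """

    b_value: float
    direction_index: int | None
    repetition_index: int | None
    slice_thickness: float
    in_plane_spacing: tuple[float, float]
    matrix_size: tuple[int, int]
    n_slices: int

    def __post_init__(self) -> None:
        if self.b_value < 0:
            raise ValidationError(f"b_value must be >= 0, got {self.b_value}")
        if self.direction_index is not None and self.direction_index < 0:
            raise ValidationError("direction_index must be >= 0")
        if self.repetition_index is not None and self.repetition_index < 0:
            raise ValidationError("repetition_index must be >= 0")
        if min(self.matrix_size) < 8:
            raise ValidationError(f"matrix dims must be >= 8, got {self.matrix_size}")
        if self.slice_thickness <= 0 or min(self.in_plane_spacing) <= 0:
            raise ValidationError("voxel spacing must be > 0")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape as ``(slice, row, col)``."""
        return (self.n_slices, self.matrix_size[0], self.matrix_size[1])

    def without_repetition(self) -> "DiffusionVolumeMeta":
        return replace(self, repetition_index=None)

    def to_dict(self) -> dict:
        return {
            "b_value": self.b_value,
            "direction_index": self.direction_index,
            "repetition_index": self.repetition_index,
            "slice_thickness": self.slice_thickness,
            "in_plane_spacing": list(self.in_plane_spacing),
            "matrix_size": list(self.matrix_size),
            "n_slices": self.n_slices,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusionVolumeMeta":
        return cls(
            b_value=float(d["b_value"]),
            direction_index=d.get("direction_index"),
            repetition_index=d.get("repetition_index"),
            slice_thickness=float(d["slice_thickness"]),
            in_plane_spacing=tuple(float(v) for v in d["in_plane_spacing"]),
            matrix_size=tuple(int(v) for v in d["matrix_size"]),
            n_slices=int(d["n_slices"]),
        )


@dataclass
class ComplexRepetitionStack:
    """Complex per-repetition slice images for one (b-value, direction).

    ``data`` is indexed ``(repetition, slice, row, col)``; all repetitions
    share the grid and diffusion weighting described by ``meta``.
    """

    data: np.ndarray
    meta: DiffusionVolumeMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 4 or self.data.shape[0] < 1:
            raise ValidationError(
                "stack data must be (repetition, slice, row, col) with >= 1 repetition"
            )
        if self.data.shape[1:] != self.meta.shape:
            raise ValidationError(
                f"stack grid {self.data.shape[1:]} does not match meta {self.meta.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack contains non-finite voxels")

    @property
    def n_repetitions(self) -> int:
        return self.data.shape[0]


@dataclass
class MagnitudeVolume:
    """Nonnegative real image in arbitrary signal units, ``(slice, row, col)``."""

    data: np.ndarray
    meta: DiffusionVolumeMeta
    provenance: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValidationError("magnitude data must be a non-empty (slice, row, col) array")
        if self.data.shape != self.meta.shape:
            raise ValidationError(
                f"volume grid {self.data.shape} does not match meta {self.meta.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite voxels")
        if np.any(self.data < 0):
            raise ValidationError("magnitude volumes must be nonnegative")
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"unknown provenance {self.provenance!r}; expected one of {PROVENANCES}"
            )


@dataclass
class ADCMap:
    """Per-voxel mono-exponential decay rate (apparent diffusion coefficient).

    ``adc`` is in mm²/s internally; ``fit_mask`` marks voxels where the fit
    was performed (background voxels get ``adc = 0`` and ``fit_mask = False``).
    """

    adc: np.ndarray
    fit_mask: np.ndarray
    meta: DiffusionVolumeMeta
    adc_max: float = 4.0e-3

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=np.float64)
        self.fit_mask = np.asarray(self.fit_mask, dtype=bool)
        if self.adc.shape != self.fit_mask.shape:
            raise ValidationError("adc and fit_mask shapes differ")
        on = self.adc[self.fit_mask]
        if on.size and (on.min() < 0 or on.max() > self.adc_max + 1e-15):
            raise ValidationError("ADC outside [0, adc_max] on fit_mask")

    def in_reporting_units(self) -> np.ndarray:
        """ADC in 10⁻⁶ mm²/s, the unit used in tabular reports."""
        return self.adc * 1.0e6


@dataclass
class S0Map:
    """Per-voxel fitted signal at b = 0 (arbitrary signal units)."""

    s0: np.ndarray
    fit_mask: np.ndarray
    meta: DiffusionVolumeMeta

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=np.float64)
        self.fit_mask = np.asarray(self.fit_mask, dtype=bool)
        if np.any(self.s0[self.fit_mask] < 0):
            raise ValidationError("S0 must be >= 0")


# ROI label codes inside the label map
ROI_LESION = 1
ROI_REFERENCE_LEFT = 2
ROI_REFERENCE_RIGHT = 3


@dataclass
class ROISet:
    """Lesion plus left/right reference ROIs on the image grid.

    ``labels`` is an integer label map (0 background, 1 lesion,
    2 left reference, 3 right reference). ``slices_used`` lists the one or
    two consecutive slice indices on which the lesion ROI was drawn.
    """

    labels: np.ndarray
    zone: str
    slices_used: tuple[int, ...]
    lesion_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.zone not in ("peripheral", "transition"):
            raise ValidationError(f"zone must be peripheral/transition, got {self.zone!r}")
        if not 1 <= len(self.slices_used) <= 2:
            raise ValidationError("slices_used must contain 1 or 2 slice indices")
        lesion_on_slices = self.labels[list(self.slices_used)] == ROI_LESION
        if not lesion_on_slices.any():
            raise ValidationError("lesion label empty on slices_used")

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask for one label, restricted to ``slices_used``."""
        m = np.zeros(self.labels.shape, dtype=bool)
        for s in self.slices_used:
            m[s] = self.labels[s] == label
        return m


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------


def _affine(meta: DiffusionVolumeMeta) -> np.ndarray:
    # axes of the stored NIfTI are (col, row, slice) after nibabel's
    # fastest-first ordering of the transposed array
    return np.diag(
        [meta.in_plane_spacing[1], meta.in_plane_spacing[0], meta.slice_thickness, 1.0]
    )


def _write_volume_file(data: np.ndarray, meta: DiffusionVolumeMeta, path: Path) -> None:
    # data has shape (..., slice, row, col); move to (col, row, slice, ...)
    arr = np.transpose(data, axes=tuple(range(data.ndim))[::-1])
    img = nib.Nifti1Image(np.ascontiguousarray(arr, dtype=np.float64), _affine(meta))
    nib.save(img, str(path))


def _read_volume_file(path: Path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    return np.transpose(arr, axes=tuple(range(arr.ndim))[::-1])


def write_complex_stack(stack: ComplexRepetitionStack, stem: Path | str) -> None:
    """Write a complex stack as ``<stem>_real.nii.gz``, ``<stem>_imag.nii.gz``
    and a ``<stem>.json`` sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _write_volume_file(stack.data.real, stack.meta, stem.parent / f"{stem.name}_real.nii.gz")
    _write_volume_file(stack.data.imag, stack.meta, stem.parent / f"{stem.name}_imag.nii.gz")
    sidecar = stack.meta.to_dict()
    sidecar["n_repetitions"] = stack.n_repetitions
    (stem.parent / f"{stem.name}.json").write_text(json.dumps(sidecar, indent=2))


def read_complex_stack(stem: Path | str) -> ComplexRepetitionStack:
    """Read a complex repetition stack written by :func:`write_complex_stack`.

    Raises
    ------
    FormatError
        If the sidecar or one of the paired volumes is missing.
    ValidationError
        If metadata invariants are violated or voxels are non-finite.
    """
    stem = Path(stem)
    sidecar_path = stem.parent / f"{stem.name}.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    meta = DiffusionVolumeMeta.from_dict(sidecar)
    real_path = stem.parent / f"{stem.name}_real.nii.gz"
    imag_path = stem.parent / f"{stem.name}_imag.nii.gz"
    if not real_path.exists() or not imag_path.exists():
        raise FormatError(f"missing real/imag volume pair for {stem}")
    real = _read_volume_file(real_path)
    imag = _read_volume_file(imag_path)
    if real.shape != imag.shape:
        raise FormatError("real and imaginary volumes have different shapes")
    data = real + 1j * imag
    if data.ndim == 3:
        data = data[None]
    if not np.all(np.isfinite(data)):
        raise ValidationError("stack contains non-finite voxels")
    if data.shape[1:] != meta.shape:
        raise ValidationError("volume grid does not match sidecar metadata")
    return ComplexRepetitionStack(data=data, meta=meta)


def write_magnitude_volume(vol: MagnitudeVolume, stem: Path | str) -> None:
    """Write a magnitude volume as ``<stem>.nii.gz`` plus JSON sidecar
    recording provenance and b-value. Refuses negative or empty arrays."""
    if vol.data.size == 0:
        raise ValidationError("refusing to write empty volume")
    if np.any(vol.data < 0):
        raise ValidationError("refusing to write negative magnitude values")
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _write_volume_file(vol.data, vol.meta, stem.parent / f"{stem.name}.nii.gz")
    sidecar = vol.meta.to_dict()
    sidecar["provenance"] = vol.provenance
    (stem.parent / f"{stem.name}.json").write_text(json.dumps(sidecar, indent=2))


def read_magnitude_volume(stem: Path | str) -> MagnitudeVolume:
    stem = Path(stem)
    sidecar_path = stem.parent / f"{stem.name}.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    data = _read_volume_file(stem.parent / f"{stem.name}.nii.gz")
    return MagnitudeVolume(
        data=data,
        meta=DiffusionVolumeMeta.from_dict(sidecar),
        provenance=sidecar["provenance"],
    )
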