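"""Quantitative lesion-detectability analysis.

Detectability of a focal lesion on DWI is quantified as the SI ratio:
mean lesion signal divided by the mean signal of normal-appearing tissue
of the same zone, the latter taken as the arithmetic mean of two circular
reference ROIs (one left, one right of the midline).  On diffusion images
a conspicuous lesion has ratio > 1 (restricted diffusion retains signal);
on ADC maps the ratio is < 1.  Ratios are scale-invariant, so they are
comparable across reconstructions with different intensity scaling.

Two reconstruction arms (standard magnitude averaging vs the complex
averaging chain) are compared pairwise per lesion: normality of the
paired differences is checked with the D'Agostino–Pearson test and the
comparison then uses the Wilcoxon signed-rank test (non-normal) or a
paired t-test (normal).  Agreement between arms is summarised with
Bland–Altman statistics (mean difference and 1.96·SD limits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dwi_eip.core import (
    ROI_LESION,
    ROI_REFERENCE_LEFT,
    ROI_REFERENCE_RIGHT,
    MagnitudeVolume,
    ROISet,
    ValidationError,
)

__all__ = [
    "DetectabilityRecord",
    "PairedComparisonResult",
    "BlandAltmanSummary",
    "roi_mean",
    "si_ratio",
    "compare_arms",
    "bland_altman",
]

IMAGE_TYPES = ("b1000", "cb2000", "adc")
ARMS = ("standard", "eip")


@dataclass
class DetectabilityRecord:
    """Per-lesion ROI means and SI ratios for every image type and arm.

    ``measurements[(image_type, arm)]`` is a dict with keys
    ``lesion_mean``, ``reference_mean``, ``ratio`` (signal units, or
    10⁻⁶ mm²/s for ADC).
    """

    lesion_id: str
    zone: str
    measurements: dict = field(default_factory=dict)

    def set(self, image_type: str, arm: str, lesion_mean: float, reference_mean: float) -> None:
        if reference_mean <= 0:
            raise ValidationError("reference_mean must be > 0")
        self.measurements[(image_type, arm)] = {
            "lesion_mean": lesion_mean,
            "reference_mean": reference_mean,
            "ratio": lesion_mean / reference_mean,
        }

    def get(self, image_type: str, arm: str, quantity: str = "ratio") -> float:
        return self.measurements[(image_type, arm)][quantity]


@dataclass(frozen=True)
class PairedComparisonResult:
    """Summary of a paired standard-vs-EIP comparison."""

    n: int
    median_standard: float
    median_eip: float
    iqr_standard: float
    iqr_eip: float
    relative_difference_of_medians: float  # (median_eip - median_std)/median_std
    median_of_relative_differences: float  # median of per-lesion (eip-std)/std
    test_used: str  # "wilcoxon_signed_rank" | "paired_t"
    p_value: float
    normality_p: float


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Mean difference and limits of agreement (mean ± 1.96·SD)."""

    mean_difference: float
    lower_limit: float
    upper_limit: float

    def __post_init__(self) -> None:
        if not self.lower_limit <= self.mean_difference <= self.upper_limit:
            raise ValidationError("limits must bracket the mean difference")


def roi_mean(volume: MagnitudeVolume | np.ndarray, roi: ROISet, label: int) -> float:
    """Mean value over all voxels of one ROI label, pooled across the one
    or two slices the ROI was drawn on."""
    data = volume.data if isinstance(volume, MagnitudeVolume) else np.asarray(volume)
    mask = roi.mask(label)
    if not mask.any():
        raise ValidationError(f"ROI label {label} empty on slices {roi.slices_used}")
    return float(data[mask].mean())


def si_ratio(lesion_mean: float, left_ref_mean: float, right_ref_mean: float) -> float:
    """SI ratio: lesion mean over the arithmetic mean of the two reference
    ROI means."""
    if left_ref_mean <= 0 or right_ref_mean <= 0:
        raise ValidationError("reference means must be > 0")
    return lesion_mean / ((left_ref_mean + right_ref_mean) / 2.0)


def measure_lesion(
    volume: MagnitudeVolume | np.ndarray, roi: ROISet
) -> tuple[float, float, float]:
    """(lesion_mean, reference_mean, ratio) for one volume and ROI set."""
    lesion = roi_mean(volume, roi, ROI_LESION)
    left = roi_mean(volume, roi, ROI_REFERENCE_LEFT)
    right = roi_mean(volume, roi, ROI_REFERENCE_RIGHT)
    return lesion, (left + right) / 2.0, si_ratio(lesion, left, right)


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def compare_arms(
    records: list[DetectabilityRecord],
    image_type: str,
    zone: str | None = None,
    quantity: str = "ratio",
    test: str = "auto",
    alpha_normality: float = 0.05,
) -> PairedComparisonResult:
    """Paired comparison of SI ratios (or ROI means) between arms.

    With ``test="auto"`` the D'Agostino–Pearson normality test on the
    paired differences selects between the Wilcoxon signed-rank test and
    the paired t-test; ``"wilcoxon"`` / ``"paired_t"`` force a choice.
    All-zero differences yield p = 1 by convention.  Requires at least 6
    pairs — below that no test has meaningful power.
    """
    if zone is not None:
        records = [r for r in records if r.zone == zone]
    std = np.array([r.get(image_type, "standard", quantity) for r in records])
    eip = np.array([r.get(image_type, "eip", quantity) for r in records])
    n = len(std)
    if n < 6:
        raise ValidationError(f"paired comparison needs >= 6 records, got {n}")
    diffs = eip - std

    if np.ptp(diffs) == 0 or n < 8:
        # constant differences (normality undefined) or too few samples
        # for the omnibus test: fall back to the rank test
        normality_p = np.nan
        selected = "wilcoxon_signed_rank"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(stats.normaltest(diffs).pvalue)
        selected = "paired_t" if normality_p >= alpha_normality else "wilcoxon_signed_rank"
    if test == "wilcoxon":
        selected = "wilcoxon_signed_rank"
    elif test == "paired_t":
        selected = "paired_t"
    elif test != "auto":
        raise ValueError(f"unknown test {test!r}")

    if np.all(diffs == 0):
        p_value = 1.0
    elif selected == "wilcoxon_signed_rank":
        p_value = float(stats.wilcoxon(eip, std, zero_method="wilcox").pvalue)
    else:
        p_value = float(stats.ttest_rel(eip, std).pvalue)

    med_std = float(np.median(std))
    med_eip = float(np.median(eip))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_lesion_rel = np.where(std != 0, diffs / std, np.nan)
    return PairedComparisonResult(
        n=n,
        median_standard=med_std,
        median_eip=med_eip,
        iqr_standard=_iqr(std),
        iqr_eip=_iqr(eip),
        relative_difference_of_medians=(med_eip - med_std) / med_std if med_std else np.nan,
        median_of_relative_differences=float(np.nanmedian(per_lesion_rel)),
        test_used=selected,
        p_value=p_value,
        normality_p=normality_p,
    )


def bland_altman(
    records: list[DetectabilityRecord],
    image_type: str,
    quantity: str = "ratio",
    zone: str | None = None,
) -> BlandAltmanSummary:
    """Bland–Altman summary of EIP − standard differences."""
    if zone is not None:
        records = [r for r in records if r.zone == zone]
    if len(records) < 2:
        raise ValidationError("Bland-Altman needs >= 2 records")
    std = np.array([r.get(image_type, "standard", quantity) for r in records])
    eip = np.array([r.get(image_type, "eip", quantity) for r in records])
    diffs = eip - std
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanSummary(
        mean_difference=mean,
        lower_limit=mean - 1.96 * sd,
        upper_limit=mean + 1.96 * sd,
    )
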