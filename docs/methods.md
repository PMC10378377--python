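# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. All voxel indices are 0-based in
`(slice, row, col)` order; ADC is carried internally in mm²/s and
converted to 10⁻⁶ mm²/s only in tabular outputs.

## Signal model

A voxel's ideal diffusion-weighted signal follows the mono-exponential
model `S(b) = S0 · exp(−b · ADC)`. Each acquired repetition is the ideal
magnitude multiplied by a spatially smooth, repetition-specific phase
error (diffusion gradients are exquisitely sensitive to microscopic
motion) plus complex Gaussian noise with standard deviation σ per
real/imaginary channel. Single-repetition magnitudes are therefore
Rician; in signal-free regions the magnitude is Rayleigh with mean
σ√(π/2) and second moment 2σ², and the voxel-wise second moment of a
noisy magnitude is `signal² + 2σ²`. Magnitude averaging preserves this
positive bias; complex averaging removes it.

## Adaptive complex combination

For each pixel, a centered k×k patch (default k = 5) is extracted per
repetition with reflect padding at image borders (the borders are a
declared choice; results are reported on interior voxels where the patch
is fully supported). Per repetition and per in-plane dimension a linear
phase coefficient is estimated as the argument of the lag-1 spatial
autocorrelation of the patch. This estimator is exact for a pure ramp
with arbitrary nonnegative amplitude and is invariant to a global phase
factor. The sign convention used here is that `estimate_linear_phase`
returns the ramp of the patch and `apply_phase_correction` multiplies by
`exp(−i Σ p_d y_d)` with coordinates centered on the patch center, so the
pair cancels the ramp and leaves the center pixel untouched.

The corrected patches are flattened into a P×R matrix A (P = k², R =
repetitions) and combined as `U[x_c,1]·σ₁/√R` from the SVD `A = U Σ V^H`.
Choices:

* **√R scaling.** The plain projection `U σ₁` grows like √R for
  identical repetitions. Dividing by √R makes the combination
  average-scaled, so images acquired with 2, 4 and 9 averages stay on a
  common intensity scale — necessary because the ADC fit and SI ratios
  mix b-values with different numbers of averages.
* **Phase convention.** The singular pair is rotated so that
  `Σ_r V[r,1]` is real nonnegative. This is irrelevant after magnitude
  extraction but makes the operation deterministic and testable.
* **Power iteration.** The leading eigenvector of the R×R Gram matrix
  `A^H A` is found by power iteration from an all-ones start, stopping
  when the relative residual `‖Gw − λw‖ ≤ 10⁻¹² λ`. Pixels that fail to
  converge within the sweep budget (near-degenerate σ₁ ≈ σ₂, essentially
  pure-noise patches) are finished with a dense Hermitian eigensolver;
  an all-zero patch combines to 0. A dense-SVD route (`full_svd`) is kept
  as an independent oracle and the two agree to better than 1e−8 on random
  stacks.
* **Implementation.** The volume operation runs as a sliding window.
  Two interchangeable implementations exist — a vectorized numpy path
  and a compiled (numba) per-pixel kernel used by default — and the test
  suite checks their agreement, so each serves as a cross-check of the
  other.

In the noiseless limit with per-repetition linear phase ramps the whole
chain is exact to floating-point precision on interior voxels; on
pure-noise backgrounds the combined mean falls to roughly half the
Rayleigh floor of magnitude averaging (the residual comes from the noise
energy captured by the leading singular direction).

## Trace images, ADC fit, computed high-b images

The trace-weighted image is the voxel-wise geometric mean over diffusion
directions — the rotation-invariant combination implied by the
mono-exponential model (no formula is universal across vendors; the
geometric mean is the standard identity). The phantom is isotropic, so
direction dependence is not simulated.

ADC and S0 come from weighted least squares on `ln S(b)` over all
acquired b-values (50, 500, 1000 s/mm²; none excluded). Default weights
are the squared signals, which approximates native-domain least squares
after the log transform; uniform weights are available. ADC is clamped
to [0, 4×10⁻³ mm²/s]. Voxels are excluded (mask false, ADC = S0 = 0)
when any b-value signal is nonpositive or the highest-b signal falls
below `2.0 × σ̂`, where σ̂ is estimated from the standard deviation of
the outermost 4-pixel border frame of the highest-b trace (Rayleigh
σ·√((4−π)/2)); the spread rather than the level is used so the estimate
vanishes on noise-free data. This border-based estimate assumes the
field of view edge is tissue-free, which holds for the phantom and for
prostate DWI FOVs but is a declared assumption.

Computed b2000 images are `S0·exp(−2000·ADC)` on the fit mask and zero
elsewhere. Masking plus clamping is the package's noise-suppression
scheme — a declared, testable stand-in for proprietary extrapolation
chains. With equal S0, the lesion/normal contrast grows from b = 1000 to
b = 2000 by exactly `exp(1000·(ADC_normal − ADC_lesion))` (≈ 2.175 for
the default peripheral-zone values), which is the mechanism by which
computed high-b images amplify lesion conspicuity.

## Registration

Repetitions of one diffusion weighting are aligned before combination,
and trace images across b-values before fitting. The backend is a
demons-style displacement estimator (SimpleITK `DemonsRegistrationFilter`)
run per slice in 2-D with Gaussian field smoothing of 2 voxels, a
3-level shrink pyramid (factors 4/2/1) and up to 50 iterations per
level; displacement magnitude is capped at 10 mm. Fields are estimated
on magnitude images and applied identically to real and imaginary
channels (phase travels with its magnitude); warping uses linear
interpolation with border extension. Cross-b registration rescales the
moving image to the reference's median tissue intensity first, since the
demons force is SSD-driven. Through-plane motion is not modelled. With
registration disabled the pipeline is exactly the deformation-free path;
the estimator recovers a known smooth 2 mm warp (as its approximate
inverse) with a large endpoint-error reduction on textured images —
uniform regions carry no gradient information, a generic limitation of
intensity-driven registration.

## Phantom

The phantom emulates a clinical prostate protocol: 114×114 matrix over a
200 mm field of view, 3 mm slices, b = 50/500/1000 s/mm² with 2/4/9
averages and 4 diffusion directions. Geometry is an elliptical
transition-zone core (semi-axes 18×13 mm) inside a peripheral-zone rim
(32×24 mm) inside zero-signal background, with spherical lesions.
Default tissue values are anchored to published prostate medians:
ADC 1.588×10⁻³ mm²/s (PZ) and 1.249×10⁻³ (TZ), lesions 0.811×10⁻³ and
0.823×10⁻³, and S0 chosen so the noiseless b1000 signal is 384 (normal
PZ), 412 (normal TZ), 495/488 (lesions). The default noise level makes
the 9-average b1000 magnitude-average background ≈ 20% of the normal
peripheral-zone signal (σ ≈ 61), which renders the hazy background
clearly. Phase errors per repetition are a linear ramp with slopes
uniform in ±0.3 rad/pixel per axis plus a random second-order polynomial
with maximum amplitude 0.5 rad (smooth, but deliberately not exactly
linear, to stress the linear-phase step) and a global phase offset.
Optional smooth random in-plane warps emulate inter-repetition motion
(off by default). Everything is reproducible from a single seed.

What the phantom does **not** model: EPI distortion and susceptibility,
anisotropic diffusion, multi-coil acquisition, perfusion (IVIM) and
kurtosis effects, realistic anatomy and through-plane motion. Passing
tests therefore demonstrate the correctness and the noise behaviour of
the algorithms, not clinical performance.

## Cohort simulation and detectability analysis

`simulate_cohort` emulates a patient cohort with one single-lesion
phantom per lesion (default 36 peripheral-zone and 20 transition-zone
lesions, the sizes of the emulated reading study), three slices per
phantom to keep desk-scale runtimes. Lesion ADC is drawn uniformly from
the published per-zone envelopes (PZ 0.4–1.2×10⁻³, TZ 0.6–1.05×10⁻³
mm²/s) and the lesion's b1000 SI ratio from the published ratio
envelopes (PZ 0.90–2.21, TZ 1.02–1.64), coupling conspicuity to the
local reference level. Both reconstruction arms run on the identical raw
data, so comparisons are strictly paired.

ROIs are placed programmatically: a 2.5 mm disc at the lesion center
(one or, for every third lesion, two consecutive slices, pooled before
averaging) and two reference discs in normal tissue of the same zone,
left and right. The SI ratio divides the lesion mean by the arithmetic
mean of the two reference means — the arithmetic mean is a declared
choice — and is scale-invariant, so the √R normalization cannot affect
detectability conclusions.

Arms are compared per (zone, image type) with the D'Agostino–Pearson
normality test on paired differences selecting between the Wilcoxon
signed-rank test and the paired t-test (forced choices available; with
fewer than 8 pairs the omnibus normality test is undefined and the rank
test is used; all-zero differences report p = 1 by convention; fewer
than 6 pairs are refused). The report emits both the relative difference
of medians and the median of per-lesion relative differences, since the
two summaries differ in skewed samples. Bland–Altman summaries use mean
difference ± 1.96 SD.

On this motion-free phantom the between-arm ratio differences are small
(fractions of a percent): the reference ROIs sit in moderate-SNR tissue
and the squared-signal weighting concentrates the ADC fit on the
high-SNR low-b images, so the Rician bias advantage of complex averaging
enters the ratios only weakly. The phantom demonstrates the ordering
effects (background suppression, contrast amplification, reduced
low-SNR ADC bias), not the clinical effect sizes, which also reflect
motion, registration and reader behaviour.

## Problem sizes and runtimes

Defaults used by the tests and the acceptance script: single-slice
phantoms for exactness/noise checks; 20 seeds for ADC bias statistics in
the test suite (10 in the acceptance script); 10+10 lesions for the
ordering check in tests and the full 36+20 cohort in the acceptance
script; 1000 replicates for statistical calibration. The full acceptance
run takes ≈ 5 minutes on one CPU.
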