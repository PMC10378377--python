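# dwi-eip

Enhanced image processing (EIP) for diffusion-weighted MRI (DWI) of the
prostate: adaptive **complex averaging** of repeated acquisitions,
trace-weighted image formation, ADC mapping, and noise-suppressed
extrapolation to **computed high-b-value images**, together with a
conventional magnitude-averaging baseline, a synthetic phantom with known
ground truth, and a quantitative lesion-detectability (SI-ratio) analysis.

## The problem

High-b-value DWI has intrinsically low SNR, so scanners acquire several
repetitions per b-value and average them. Because diffusion gradients
induce unpredictable smooth phase errors, the *magnitude* is averaged,
which discards phase and leaves a positive Rician noise bias: in
signal-free regions the averaged magnitude settles at the Rayleigh floor
σ√(π/2) instead of zero, visible as a hazy background that degrades
lesion conspicuity — directly on acquired b1000 images and, amplified,
on computed b2000 images extrapolated from them.

## The method

For every pixel `x_c`, a centered 5×5 patch `I_r(x)` is taken from each
repetition `r`. A linear phase ramp is estimated per dimension `d` from
the lag-1 spatial autocorrelation

    p_d = arg Σ_y conj(I_r(y)) · I_r(y + Δ_d)

and removed by pixel-wise multiplication with `exp(-i Σ_d p_d x_d)`.
The corrected patches are flattened into a matrix `I_{x,r}`, its SVD
`I = U Σ V^H` is computed (in practice via power iteration on the R×R
Gram matrix, with a dense eigensolver fallback for near-degenerate
patches), and the combined value is the projection on the largest
singular direction, `U_{x_c,1}·σ_1`, here scaled by `1/√R` so the result
is commensurate with a plain average. Because noise is zero-mean in the
complex domain, the combined image has no Rayleigh floor.

Downstream, trace-weighted images (geometric mean over diffusion
directions) at b = 50/500/1000 s/mm² feed a per-voxel weighted
least-squares fit of `ln S(b) = ln S0 − b·ADC`, and computed b2000 images
are synthesized as `S0·exp(−2000·ADC)` with background masking and ADC
clamping for noise suppression. Non-rigid (demons-style) registration
aligns repetitions before combination and traces across b-values before
fitting. Lesion detectability is quantified as the SI ratio: mean lesion
signal over the mean of two reference ROIs in normal tissue of the same
zone, compared between reconstructions with Wilcoxon/paired-t tests and
Bland–Altman limits of agreement.

## Worked example

Simulate a small cohort of single-lesion phantoms (the emulated protocol:
114×114 matrix, b = 50/500/1000 s/mm² with 2/4/9 averages, 4 directions),
reconstruct both arms from identical raw data, and compare SI ratios:

```python
from dwi_eip.pipeline import simulate_cohort, summarize_cohort

records = simulate_cohort(n_pz=8, n_tz=6, seed=42)
for row in summarize_cohort(records):
    print(f"{row['zone']:<11} {row['image_type']:<7} n={row['n']:>2}  "
          f"median std={row['median_standard']:.3f}  eip={row['median_eip']:.3f}  "
          f"rel diff={100*row['relative_difference_of_medians']:+.2f}%  "
          f"{row['test_used']} p={row['p_value']:.3f}")
```

prints

```
peripheral  b1000   n= 8  median std=1.548  eip=1.557  rel diff=+0.60%  paired_t p=0.001
peripheral  cb2000  n= 8  median std=2.878  eip=2.903  rel diff=+0.85%  paired_t p=0.009
peripheral  adc     n= 8  median std=0.618  eip=0.619  rel diff=+0.20%  paired_t p=0.948
transition  b1000   n= 6  median std=1.382  eip=1.388  rel diff=+0.43%  wilcoxon_signed_rank p=0.031
transition  cb2000  n= 6  median std=2.163  eip=2.175  rel diff=+0.57%  wilcoxon_signed_rank p=0.031
transition  adc     n= 6  median std=0.679  eip=0.678  rel diff=-0.08%  wilcoxon_signed_rank p=0.156
```

Read: lesion/normal SI ratios are larger on computed b2000 than on
acquired b1000 in both zones (contrast amplification by extrapolation),
ADC ratios sit below 1 (restricted diffusion in lesions), and the
complex-averaging arm shows slightly higher detectability ratios than the
magnitude-averaging arm on this motion-free phantom.

A command-line interface mirrors the library:

```sh
dwi-eip simulate --out sim/ --seed 1
dwi-eip reconstruct --method complex --in sim/ --out recon/
dwi-eip run --out runs/demo --seed 1
```

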