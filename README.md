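# nanovario

Variogram-based nanoscale texture analysis of AFM height maps of
histological sections.

## The problem

Atomic force microscopy images of tissue sections (square rasters of
z-heights, e.g. 50 μm × 50 μm at 512 × 512 points, 97.7 nm/pixel) carry
sub-micrometre texture that plain visual inspection and whole-image
roughness statistics miss.  In colorectal-cancer histology, sections
containing metastatic (mesenchymal-like, smoother) cells show *lower*
fine-scale roughness than non-metastatic (epithelial-like, rougher)
sections.  `nanovario` quantifies that contrast and turns it into a
numerical index:

1. **Gaussian residual.**  The height field is split into a smoothed part
   and a high-pass residual, `r = z − G_σ * z`, with a separable Gaussian
   kernel truncated at the 6σ+1 box (σ = 5 px → 31 px kernel).  The
   residual carries the sub-kernel-scale roughness.
2. **Variograms.**  For each integer lag vector `h = (v, p)` the RMS
   deviation is

       D(h) = sqrt( (1/N) Σ [r(x_i, y_j) − r(x_i+v, y_j+p)]² ),

   with `N = (n−|v|)(n−|p|)` in-bounds pairs.  Radial pooling over
   `|h| = sqrt(v²+p²)` gives the empirical variogram; the generalized
   moment variogram is `γ(h, q) = B(h)^q`, where `B` is the per-bin mean
   squared difference (`q = 0.5` is exactly `D`, in μm).
3. **Sill index.**  Each curve flattens to a *sill* once lags decorrelate;
   the sill (plateau mean over the trailing 30% of lags) is the
   per-sample metastatic index.
4. **Threshold classifier.**  The threshold is the median (midpoint) of
   the two labelled group-mean sills; samples above it are called
   non-metastatic, below it metastatic.  Group separation is tested with
   a Welch two-sample t-test, and a moment sweep over
   q ∈ {0.5, 1, 2, 3, 4, 5} tracks how the relative group gap grows with
   the moment.
5. **Supporting markers and baselines.**  Facet-inclination ("theta")
   statistics (θ = arctan|∇z|, skewness/kurtosis of the angle sample),
   plus the classical battery: surface moments, rescaled-range Hurst
   exponents (Anis–Lloyd-corrected R/S, whole-image and per-line), and
   four monofractal dimension estimators (cube counting, triangulation,
   power spectrum, partition).

Because patient rasters are not redistributable, the package ships a
first-class synthetic-surface module: analytic fixtures, spectrally
synthesized fractional Brownian surfaces with known Hurst exponent
(PSD ∝ f^−(2H+2), D_f = 3 − H), and two-class tissue phantoms whose only
difference is the RMS of a sub-micrometre speckle texture — exactly the
band the Gaussian residual isolates.

## Worked example

```python
from nanovario import (
    FilterSpec, SurfaceSpec, estimate_sill, gaussian_residual,
    generate_cohort, radial_variogram,
)
from nanovario.pipeline import PipelineConfig, analyze_cohort, classify_cohort

# an 18-section synthetic cohort: 11 metastatic-like (smooth),
# 7 non-metastatic-like (rough), 512 px / 50 um each
cohort = generate_cohort(11, 7, seed=1)

cfg = PipelineConfig(include_baselines=False)   # sigma = 5 px, q = 0.5..5
features, records = analyze_cohort(cohort, cfg)
report, results = classify_cohort(records, cfg)
row = report[report.q == 0.5].iloc[0]
print(f"group mean sills: met {row.group_mean_met:.3f} um, "
      f"non-met {row.group_mean_nonmet:.3f} um")
print(f"threshold {row.threshold:.3f} um, correct calls "
      f"{row.n_correct}/{row.n_labelled}, Welch p = {row.p_value:.2e}")
```

prints

```
group mean sills: met 0.079 um, non-met 0.161 um
threshold 0.120 um, correct calls 18/18, Welch p = 9.13e-08
```

i.e. the smoother metastatic-like group sits at roughly half the sill of
the rougher group, the midpoint threshold separates all 18 samples, and
the group difference is significant at p ≈ 1e-7.  The same report at
higher moments shows the relative group gap growing with q
(`separation_rel` column).

A shell workflow is available too:

```bash
nanovario simulate --out cohort/ --n-met 11 --n-nonmet 7 --seed 1
nanovario run --manifest cohort/manifest.csv --out results/
nanovario variogram cohort/m1.1.txt
```

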