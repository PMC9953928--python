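# Methods

This note records the models, conventions, defaults and known
limitations behind `nanovario`.

## Data model and geometry

A `HeightMap` is a square raster of finite z-values with a physical pixel
size (μm), a channel tag (height, amplitude, phase) and value units (μm
for height/amplitude, degrees for phase).  The coordinate frame is fixed:
row-major, origin top-left, x = column, y = row, 0-based; all lag vectors
are expressed in this frame so directional quantities are reproducible.
A 50 μm scan at 512 points has 97.65625 nm pixels (printed as 97.7 nm).
Multi-resolution analysis (512/256/128 px) is produced by block-mean
decimation, which is anti-aliased and preserves the grid mean exactly;
whether a re-scan or decimation is used matters only below the
decimation block size.

On-disk formats are text-first (whitespace matrix or float TIFF plus a
YAML sidecar with scan size/channel/units).  No vendor binary formats,
and deliberately no plane/line levelling or background subtraction: the
Gaussian residual itself removes large-scale relief, and levelling would
alter the very fine-scale statistics being measured.

## Gaussian residual

The filter is a 2D separable Gaussian over the scalar z-field with equal
σ on both axes.  The kernel is truncated exactly at the nearest odd
integer to 6σ+1 (ties round up), so σ = 5 px gives a 31-px box; weights
are normalized to sum to one.  The residual (original − smoothed) is a
high-pass field retaining structure below the kernel box (~3 μm at
σ = 5 px and 97.7 nm pixels), with some spectral leakage.  Boundary
handling defaults to reflection, which avoids edge ramps that would
inflate residual sills; nearest and wrap are available.  σ can be given
in pixels or micrometres (converted by the raster's pixel size) —
holding σ fixed in micrometres is what makes sills comparable across
resolutions.

## Variograms and sills

The per-lag quantity is the mean squared difference over all in-bounds
pairs at signed lag (v, p), computed via one zero-padded FFT
autocorrelation plus prefix-sum corner rectangles; this equals the
exhaustive double loop to floating precision (the suite checks 1e-12
relative on small rasters) and is exactly centrosymmetric.  The grand
mean is subtracted first (the statistic is offset-invariant), so
constant fields give exact zeros.  RMS deviation D is the square root,
in the units of z.

Radial curves pool all directions: squared differences of every lag with
|h| in a bin are pair-count weighted, so the per-bin base B equals the
grand mean of squared differences in the bin.  Defaults: bin width 1 px,
maximum lag n/4 px (keeps ≥ 75% pair overlap and covers the plateau
regime).  The moment-q curve is γ(h, q) = B^q; q = 0.5 is the μm-valued
RMS-deviation curve, q = 1 the classical empirical variogram (μm²).
Per-lag, γ(h, q) = γ(h, 1)^q identically — the moments carry no new
per-lag information; their discriminative value arises from how the
power transform interacts with plateau averaging and group thresholds.
Because B^q crosses 1 differently depending on units, moment profiles
are only comparable across samples at matched q and units.

The sill is estimated as the pair-count-weighted mean of γ over the
trailing 30% of the lag domain (`plateau_fraction = 0.3`), a simple
deterministic surrogate for "where the curve flattens off".  A linear
fit over the window yields a relative slope; above a cap (default 0.1)
the estimate is flagged `rising` rather than rejected — drifting
surfaces (e.g. planes) have no sill and are flagged.  Empty bins are
excluded; at least five non-empty bins are required.

## Theta statistics

Each interior pixel defines the smallest planar facet the grid supports;
its inclination is θ = arctan|∇z| in degrees with central-difference
gradients over physical coordinates.  An optional k×k least-squares
plane-fit facet exists for coarser facets (default is 1-pixel facets —
the smallest "tiny planar segment" consistent with the data).  The
histogram covers [0°, 90°] with 1° bins by default; skewness and excess
kurtosis (Fisher convention, normal = 0) are computed from the raw angle
sample, never from the binned histogram.  θ is invariant to z-offsets
and equivariant under z-rescaling (θ → arctan(k·tanθ)).

## Baselines

*Surface statistics*: mean, RMS roughness (standard deviation about the
mean), skewness, excess kurtosis, min/max of the z-sample;
channel-agnostic (phase rasters give phase statistics).

*Rescaled range*: classic R/S over a dyadic window ladder (8 … len/4,
≥ 4 sizes).  Raw R/S is biased upward at practical window sizes
(≈ 0.54 for iid noise even at length 65536), so the default estimator
subtracts the Anis–Lloyd expected iid R/S (with the small-n Peters
prefactor) in log space and adds the deviation slope to 1/2; the naive
slope is available via `corrected=False`.  Image lines are height
*profiles* — non-stationary with stationary increments — so
`hurst_image` differences each series before R/S and the fitted exponent
estimates the profile Hurst exponent.  Two variants: one
row-concatenated n² series (one spurious increment per row seam,
negligible at n ≥ 128 but note that spectrally synthesized periodic
surfaces make row sums nearly close, which deflates the long-window
slope — the two variants are *expected* to differ), and one H per row
with the across-row mean and distribution.

*Fractal dimensions*: four standard estimators with log-log fits over
dyadic scale ladders, validated on synthetic fBm via D = 3 − H rather
than against any per-sample values:

- cube counting — N(ε) lattice boxes intersected per column block;
  D = −dlogN/dlogε.  The z-range is normalized to the lateral extent
  times a vertical-exaggeration factor (default 16) and the ladder runs
  8 … n/4 px: the exaggeration keeps the count on the relief scaling law
  instead of the flat-surface floor N ∝ ε⁻², and blocks below 8 px
  under-resolve the relief range of a sampled surface.  Both choices
  mitigate the well-known downward bias of box dimensions on self-affine
  surfaces; residual accuracy is about ±0.1 at H = 0.5 on 256-px fBm.
- triangulation — triangulated area A(s) on step-s subgrids
  (z-range normalized to the lateral extent); D = 2 − dlogA/dlogs.  The
  area is renormalized to the full lateral domain at every step because
  a step-s subgrid covers only ((m−1)s)² of the raster; without this a
  tilted plane reads ≈ 2.2 instead of exactly 2.
- power spectrum — radially averaged periodogram slope β between the 3rd
  radial bin and half the Nyquist frequency; D = 4 − β/2.
- partition — mean within-box variance V(s) ∝ s^2H; D = 3 − slope/2.

Estimates are clamped to [2, 3] with a flag.  Constant surfaces give
exactly 2 for the counting/triangulation methods and raise for the
spectral/partition methods.

## Threshold classifier

Per-sample sills (per moment q) feed a one-dimensional rule: threshold =
median of the two labelled group means (= midpoint for two groups;
median generalizes if more groups are ever configured).  Sill above
threshold → non-metastatic call; ties are called non-metastatic
(conservative toward follow-up screening) and flagged.  The orientation
assumption (non-metastatic mean > metastatic mean) is checked and a
violation flagged as `inverted`.  Group separation is tested with a
two-sided two-sample t-test on labelled sills — Welch by default
(unequal group sizes, no evidence of equal variances), Student's pooled
variant by configuration.  Rescaling all sills by k > 0 rescales the
threshold by k and leaves every call unchanged.

The moment sweep reports two separation measures per q:
`separation_rel` — the group-mean gap relative to the smaller group mean
— and `separation_d` — gap over pooled standard deviation.  For groups
whose plateau levels differ by a ratio with multiplicative within-group
dispersion, `separation_rel` grows monotonically with q while
`separation_d` does not (the power transform inflates the within-group
spread faster than the gap); monotonicity statements therefore refer to
`separation_rel`, and both are reported.  Sweep p-values are uncorrected
by default (one headline test per feature); a Bonferroni option exists.
A borderline sample between the group means can change sides as q grows
because the max-dominated group means shift the midpoint; with this
threshold rule the flip direction is toward the metastatic side.

Theta-skewness calls are a secondary sign rule (positive skewness →
metastatic-like) with a reported agreement rate.

## Synthetic surfaces

All generators are seed-deterministic (identical spec ⇒ bit-identical
surface).

*Analytic fixtures*: constant fields, planes (z = a·x exactly), sine
ridges, white noise.

*Fractional Brownian surfaces*: spectral synthesis — white real noise
filtered in the Fourier domain by the radial gain f^−(H+1), giving
PSD ∝ f^−(2H+2) with exact Hermitian symmetry and hence a known ground
truth for the spectral estimator (periodogram slope recovers H within
±0.1 at n ≥ 256) and for D = 3 − H.

*Tissue phantoms*: offset + large-scale relief + fine speckle texture.
The relief is Gaussian-correlated noise with a 10 μm correlation length
(≫ the ~3 μm filter cut-off) and RMS `amplitude` (default 0.8 μm),
plus a constant offset (2.5 × amplitude) so heights stay positive like
real AFM data; both phantom classes generated from one seed share the
relief exactly.  The texture is white noise smoothed to a 0.35 μm
correlation length and scaled to `fine_texture_rms` (default 0.19 μm);
the smooth (metastatic-like) class divides this RMS by the fixed class
contrast 2.0.  Correlated speckle rather than per-pixel noise is
essential: per-pixel noise loses ~16× variance under 512→128 block-mean
decimation, whereas physical sub-micrometre texture survives it, which
is what makes sills resolution-invariant at matched σ in micrometres
(measured spread ≈ 6%, versus the 10% documentation bound).  In cohorts
each sample draws its own seed and a lognormal jitter (σ = 0.12) on the
fine-texture RMS, giving within-group sill dispersion of roughly the
size implied by one borderline sample in an 18-section study.

What the phantoms do *not* model: cell morphology, nuclei, ECM fibres,
scanner artifacts (drift, scars), or tip convolution.  They reproduce
only second-order texture statistics, so a passing cohort study shows
the pipeline recovers a known fine-scale contrast — not that real
metastatic tissue will show the same effect size.

Two default-phantom behaviours worth noting.  First, with σ = 5 px at
512 px the group-mean residual sills come out near 0.08/0.16 μm; real
tissue values depend on the texture actually present and are not
matched.  Second, facet-angle skewness is positive for *both* phantom
classes (smooth class larger): the direction of the sign-based theta
call is a property of the texture model, not a universal law, so on
default phantoms only the between-class ordering of skewness is
meaningful.

## Statistical caveats

With 11 + 7 samples per cohort, the Welch test on μm-scale sills (the
q = 0.5 channel) yields p between 1e-8 and 1e-4 across cohort seeds at
the default dispersion; on the μm²-scale q = 1 sills the squared units
fatten the within-group upper tail and p fluctuates around 1e-4.  The
significance of the group split is therefore quoted on the μm-scale sill
index.  Accuracy, by contrast, is stable: ≥ 17/18 on every seed
examined, usually 18/18.

## Problem sizes

Defaults used by the test suite and the acceptance script: 512-px
cohorts (18 samples × 5 seeds) for the classification study; 256-px
surfaces and 10 seeds for stochastic limits (white-noise sill, fBm
Hurst), 5 seeds for fractal dimensions; 65536-point series for R/S.
These sizes put Monte Carlo scatter well inside the documented bands
while keeping a full run in tens of seconds on one CPU.
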