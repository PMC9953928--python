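"""Comparison battery: surface statistics, rescaled-range Hurst analysis,
and monofractal surface-dimension estimators.

These are the classical whole-image texture measures against which the
Gaussian-residual variogram indexes are compared.  They apply to any
channel (height, amplitude or phase rasters alike).

Hurst analysis
--------------
``hurst_rescaled_range`` implements classic R/S on a stationary series:
for each window size w, the series is cut into disjoint windows; in each,
the range of cumulative mean-adjusted sums is divided by the window
standard deviation; H is the slope of log2(mean R/S) vs log2(w) over a
dyadic window ladder (default 8 .. len/4).  Raw R/S is biased upward for
the short windows every practical ladder contains, so by default the
Anis-Lloyd expected R/S of an iid series (with the small-n Peters
prefactor) is subtracted in log space and the fitted deviation slope is
added to 1/2 — the standard finite-sample correction; ``corrected=False``
restores the naive slope.  For image lines, which are *profiles*
(non-stationary, stationary increments), ``hurst_image`` differences the
series first so the fitted exponent is the profile's Hurst exponent; two
variants exist: one long row-concatenated series, or one H per row with
the across-row distribution.

Fractal dimension
-----------------
Four standard estimators of the monofractal surface dimension
D_f in [2, 3] (the set familiar from SPM analysis software):

- ``cube_counting``: N(eps) boxes of size eps intersected by the surface,
  D_f = -dlogN/dlog(eps).
- ``triangulation``: triangulated surface area A(s) at grid step s,
  D_f = 2 - dlogA/dlog(s); the area is renormalized to the full lateral
  domain at every step (the covered extent of a subsampled grid varies
  with s and would otherwise tilt the fit — a tilted plane must give
  exactly 2).
- ``power_spectrum``: radially averaged periodogram P(f) ~ f**-beta,
  D_f = 4 - beta/2 (for a self-affine surface beta = 2H + 2 and
  D_f = 3 - H).
- ``partition``: mean within-box variance V(s) ~ s**(2H),
  D_f = 3 - H.

Box/triangle counting of a *physical* surface depends on the z-aspect
convention, so for cube counting and triangulation the z-range is first
rescaled to the lateral extent (in pixel units) times a configurable
aspect factor ``z_aspect``.  For cube counting the default aspect is 16
and the scale ladder starts at 8 px: a vertical-dominant aspect keeps
the count scaling on the relief law instead of the flat-surface floor
N ~ eps**-2, and the smallest blocks under-resolve the relief range on a
sampled grid; both choices reduce the well-known downward bias of box
dimensions on self-affine surfaces.  All estimators are invariant to
adding a constant to z.  Estimates are clamped to [2, 3] with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateSurfaceError, ParameterError
from .raster_io import HeightMap

__all__ = [
    "SurfaceStats",
    "HurstResult",
    "FractalDimEstimate",
    "surface_stats",
    "hurst_rescaled_range",
    "hurst_image",
    "fractal_dimension",
    "radial_power_spectrum",
    "estimate_hurst_periodogram",
]

FRACTAL_METHODS = ("cube_counting", "triangulation", "power_spectrum", "partition")


@dataclass
class SurfaceStats:
    """First moments of the z-value sample of one raster."""

    mean_z: float
    rms_roughness: float  # standard deviation of z about its mean
    z_skewness: float
    z_kurtosis: float  # excess (Fisher)
    z_min: float
    z_max: float


@dataclass
class HurstResult:
    """Rescaled-range Hurst estimate.

    ``method`` is ``series``, ``concatenated`` or ``per_line``; for
    ``per_line`` the per-row exponents are kept and ``H`` is their mean.
    """

    method: str
    H: float
    window_sizes: np.ndarray
    fit_r2: float
    rs_values: np.ndarray | None = None
    per_line_H: np.ndarray | None = None


@dataclass
class FractalDimEstimate:
    """Monofractal surface dimension from one scaling-law estimator."""

    method: str
    D_f: float
    fit_range: tuple[float, float]
    fit_r2: float
    clamped: bool = False
    z_rescaled: bool = False


def surface_stats(hmap: HeightMap) -> SurfaceStats:
    """Moments of the z-sample (channel-agnostic).

    Shape moments of a (near-)constant sample are undefined and reported
    as NaN.
    """
    z = hmap.values.ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = float(stats.skew(z))
        kurt = float(stats.kurtosis(z))
    return SurfaceStats(
        mean_z=float(z.mean()),
        rms_roughness=float(z.std()),
        z_skewness=skew,
        z_kurtosis=kurt,
        z_min=float(z.min()),
        z_max=float(z.max()),
    )


def _dyadic_windows(length: int, w_min: int = 8) -> np.ndarray:
    w_max = length // 4
    sizes = []
    w = w_min
    while w <= w_max:
        sizes.append(w)
        w *= 2
    return np.asarray(sizes, dtype=int)


def expected_rs(n: int) -> float:
    """Anis-Lloyd expected R/S of an iid series of length n.

    Uses the Peters prefactor ``(n - 1/2)/n`` and the exact
    Gamma-function constant for n <= 340 (log-Gamma for stability), its
    asymptotic form above.
    """
    i = np.arange(1, n)
    tail = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        c = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
    else:
        c = 1.0 / np.sqrt(n * np.pi / 2.0)
    return float((n - 0.5) / n * c * tail)


def _rs_per_window(segs: np.ndarray) -> np.ndarray:
    """Mean R/S over the rows of a (n_windows, w) array; NaN if all degenerate."""
    dev = segs - segs.mean(axis=-1, keepdims=True)
    cum = np.cumsum(dev, axis=-1)
    r = cum.max(axis=-1) - cum.min(axis=-1)
    s = segs.std(axis=-1, ddof=1)
    valid = s > 0
    if not np.any(valid):
        return np.nan
    return float(np.mean(r[valid] / s[valid]))


def hurst_rescaled_range(
    series: np.ndarray,
    window_sizes: np.ndarray | None = None,
    corrected: bool = True,
) -> HurstResult:
    """Classic R/S Hurst exponent of a stationary 1D series.

    Windows default to dyadic sizes from 8 to len/4; at least 4 sizes are
    required for the log-log fit.  Zero-variance windows are skipped; a
    window size where all windows are degenerate is dropped, and if all
    sizes drop an error is raised.  With ``corrected=True`` (default) the
    Anis-Lloyd expected iid R/S is subtracted in log space and the
    deviation slope added to 1/2, removing the short-window upward bias.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size < 64:
        raise ParameterError(f"series must have >= 64 samples, got {x.size}")
    if window_sizes is None:
        window_sizes = _dyadic_windows(x.size)
    window_sizes = np.asarray(window_sizes, dtype=int)
    if np.any(window_sizes < 8):
        raise ParameterError("window sizes must be >= 8 samples")
    if len(window_sizes) < 4:
        raise ParameterError("need >= 4 window sizes for the log-log fit")

    rs = []
    used = []
    for w in window_sizes:
        k = x.size // w
        if k < 1:
            continue
        val = _rs_per_window(x[: k * w].reshape(k, w))
        if np.isfinite(val):
            rs.append(val)
            used.append(w)
    if len(rs) < 4:
        raise DegenerateSurfaceError("too few non-degenerate windows for an R/S fit")
    used = np.asarray(used)
    rs = np.asarray(rs)
    y = np.log2(rs)
    if corrected:
        y = y - np.log2([expected_rs(w) for w in used])
    slope, intercept, r, _, _ = stats.linregress(np.log2(used), y)
    h = slope + 0.5 if corrected else slope
    return HurstResult(
        method="series",
        H=float(h),
        window_sizes=used,
        fit_r2=float(r**2),
        rs_values=rs,
    )


def _per_line_hurst(rows: np.ndarray, window_sizes: np.ndarray) -> np.ndarray:
    """Vectorized Anis-Lloyd-corrected R/S exponent per row."""
    n_rows, length = rows.shape
    log_e = np.log2([expected_rs(w) for w in window_sizes])
    log_rs = np.full((len(window_sizes), n_rows), np.nan)
    for wi, w in enumerate(window_sizes):
        k = length // w
        segs = rows[:, : k * w].reshape(n_rows, k, w)
        dev = segs - segs.mean(axis=-1, keepdims=True)
        cum = np.cumsum(dev, axis=-1)
        r = cum.max(axis=-1) - cum.min(axis=-1)
        s = segs.std(axis=-1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rs = np.where(s > 0, r / s, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_rs = np.nanmean(rs, axis=-1)
        log_rs[wi] = np.log2(mean_rs) - log_e[wi]
    lw = np.log2(window_sizes.astype(float))
    # least-squares deviation slope per row, tolerating NaN windows
    out = np.full(n_rows, np.nan)
    for j in range(n_rows):
        y = log_rs[:, j]
        ok = np.isfinite(y)
        if ok.sum() >= 4:
            out[j] = np.polyfit(lw[ok], y[ok], 1)[0] + 0.5
    return out


def hurst_image(hmap: HeightMap, method: str = "per_line") -> HurstResult:
    """Hurst exponent of an image's scan lines.

    Image rows are height *profiles*; their first differences are the
    stationary increment series R/S assumes, so each series is
    differenced before the R/S ladder and the fitted exponent estimates
    the profile Hurst exponent.

    ``concatenated`` strings all rows into one n^2-point series (one
    spurious increment per row seam, negligible for n >= 128) and fits a
    single H.  ``per_line`` fits one H per row and reports the mean plus
    the across-row distribution.
    """
    z = hmap.values
    n = z.shape[0]
    if method == "concatenated":
        series = np.diff(z.reshape(-1))
        res = hurst_rescaled_range(series)
        return HurstResult(
            method="concatenated",
            H=res.H,
            window_sizes=res.window_sizes,
            fit_r2=res.fit_r2,
            rs_values=res.rs_values,
        )
    if method == "per_line":
        inc = np.diff(z, axis=1)
        # ladder from the row length (differencing drops one sample but
        # should not cost the top window of a power-of-two row)
        windows = _dyadic_windows(z.shape[1])
        if len(windows) < 4:
            raise ParameterError(f"rows of length {n} give too few R/S windows")
        per_line = _per_line_hurst(inc, windows)
        ok = np.isfinite(per_line)
        if not np.any(ok):
            raise DegenerateSurfaceError("no row admitted an R/S fit")
        return HurstResult(
            method="per_line",
            H=float(np.mean(per_line[ok])),
            window_sizes=windows,
            fit_r2=float("nan"),
            per_line_H=per_line,
        )
    raise ParameterError(f"method must be 'concatenated' or 'per_line', got {method!r}")


def _dyadic_scales(n: int, lo: int = 2) -> np.ndarray:
    scales = []
    s = lo
    while s <= n // 4:
        scales.append(s)
        s *= 2
    return np.asarray(scales, dtype=int)


def _normalize_z(z: np.ndarray, n: int) -> np.ndarray:
    zr = z.max() - z.min()
    if zr == 0:
        raise DegenerateSurfaceError("constant surface: no z-range to rescale")
    return (z - z.min()) * (n / zr)


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept, r, _, _ = stats.linregress(np.log(x), np.log(y))
    return float(slope), float(r**2)


def fractal_dimension(
    hmap: HeightMap,
    method: str,
    scales: np.ndarray | None = None,
    z_aspect: float = 16.0,
) -> FractalDimEstimate:
    """Monofractal surface dimension by one of the four standard methods.

    Default scale ladders are dyadic up to n/4 px, starting at 8 px for
    cube counting (smaller blocks under-resolve the relief range of a
    sampled surface), 1 px for triangulation and 2 px for partitioning;
    the power spectrum fits radial frequencies between the 3rd bin and
    half the Nyquist frequency.  ``z_aspect`` sets the vertical
    exaggeration applied after range normalization for cube counting
    (dimensionality of a physical surface depends on the z-aspect
    convention; the default keeps the surface vertical-dominant over the
    counted scales).  A degenerate (constant) surface yields D_f = 2
    exactly for triangulation and cube counting and raises for the
    spectral/partition methods (no scaling law to fit).
    """
    if method not in FRACTAL_METHODS:
        raise ParameterError(f"method must be one of {FRACTAL_METHODS}, got {method!r}")
    z = hmap.values
    n = hmap.n_px
    if n < 64:
        raise ParameterError(f"need n >= 64 for a stable fractal fit, got {n}")

    degenerate = z.max() == z.min()

    if method == "cube_counting":
        if scales is None:
            scales = _dyadic_scales(n, lo=8)
        scales = np.asarray(scales, dtype=int)
        if degenerate:
            return FractalDimEstimate(method, 2.0, (float(scales[0]), float(scales[-1])), 1.0, z_rescaled=True)
        zn = _normalize_z(z, n) * z_aspect
        counts = []
        for s in scales:
            m = n // s
            blocks = zn[: m * s, : m * s].reshape(m, s, m, s)
            zmin = blocks.min(axis=(1, 3))
            zmax = blocks.max(axis=(1, 3))
            counts.append(np.sum(np.floor(zmax / s) - np.floor(zmin / s) + 1))
        slope, r2 = _loglog_fit(scales, np.asarray(counts, dtype=float))
        d = -slope
        return _clamp(method, d, scales, r2, z_rescaled=True)

    if method == "triangulation":
        if scales is None:
            scales = _dyadic_scales(n, lo=1)
        scales = np.asarray(scales, dtype=int)
        if degenerate:
            return FractalDimEstimate(method, 2.0, (float(scales[0]), float(scales[-1])), 1.0, z_rescaled=True)
        zn = _normalize_z(z, n)
        areas = []
        for s in scales:
            g = zn[::s, ::s]
            m = g.shape[0]
            a = g[:-1, :-1]
            b = g[:-1, 1:]
            c = g[1:, :-1]
            dd = g[1:, 1:]
            # two triangles per cell, lateral edge s
            t1 = 0.5 * np.sqrt((s * (a - b)) ** 2 + (s * (a - c)) ** 2 + float(s) ** 4)
            t2 = 0.5 * np.sqrt((s * (dd - b)) ** 2 + (s * (dd - c)) ** 2 + float(s) ** 4)
            # renormalize to the full lateral domain: the extent covered
            # by a step-s subgrid, ((m-1)*s)^2, varies with s and would
            # otherwise tilt the fit (a plane must give exactly D = 2)
            covered = float((m - 1) * s) ** 2
            areas.append((t1.sum() + t2.sum()) * (n * n / covered))
        slope, r2 = _loglog_fit(scales, np.asarray(areas))
        d = 2.0 - slope
        return _clamp(method, d, scales, r2, z_rescaled=True)

    if method == "power_spectrum":
        if degenerate:
            raise DegenerateSurfaceError("constant surface has no power-spectrum slope")
        freqs, power = radial_power_spectrum(hmap)
        nyq = 0.5 / hmap.pixel_size
        sel = (freqs >= freqs[2]) & (freqs <= 0.5 * nyq) & (power > 0)
        if sel.sum() < 4:
            raise DegenerateSurfaceError("too few spectral bins for a slope fit")
        slope, r2 = _loglog_fit(freqs[sel], power[sel])
        beta = -slope
        d = 4.0 - beta / 2.0
        return _clamp(method, d, (float(freqs[sel][0]), float(freqs[sel][-1])), r2)

    # partition: mean within-box variance V(s) ~ s^(2H), D = 3 - H
    if scales is None:
        scales = _dyadic_scales(n, lo=2)
    scales = np.asarray(scales, dtype=int)
    if degenerate:
        raise DegenerateSurfaceError("constant surface has no partition scaling")
    variances = []
    used = []
    for s in scales:
        m = n // s
        blocks = z[: m * s, : m * s].reshape(m, s, m, s)
        v = blocks.var(axis=(1, 3)).mean()
        if v > 0:
            variances.append(v)
            used.append(s)
    if len(used) < 3:
        raise DegenerateSurfaceError("too few scales with nonzero variance")
    slope, r2 = _loglog_fit(np.asarray(used, dtype=float), np.asarray(variances))
    d = 3.0 - slope / 2.0
    return _clamp("partition", d, np.asarray(used), r2)


def _clamp(method: str, d: float, scales, r2: float, z_rescaled: bool = False) -> FractalDimEstimate:
    if isinstance(scales, tuple):
        fit_range = scales
    else:
        fit_range = (float(scales[0]), float(scales[-1]))
    clamped = not (2.0 <= d <= 3.0)
    return FractalDimEstimate(
        method=method,
        D_f=float(np.clip(d, 2.0, 3.0)),
        fit_range=fit_range,
        fit_r2=r2,
        clamped=clamped,
        z_rescaled=z_rescaled,
    )


def radial_power_spectrum(hmap: HeightMap) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged 2D periodogram.

    Returns ``(freqs, power)`` where ``freqs`` are annulus-center radial
    frequencies in cycles per micrometre (bin width = the fundamental
    frequency 1/scan_size) and ``power`` is the mean periodogram value in
    each annulus.  The DC bin is excluded.
    """
    z = hmap.values - hmap.values.mean()
    n = hmap.n_px
    spec = np.abs(np.fft.fft2(z)) ** 2 / (n * n)
    f1d = np.fft.fftfreq(n, d=hmap.pixel_size)
    fx, fy = np.meshgrid(f1d, f1d)
    fr = np.hypot(fx, fy)
    df = 1.0 / hmap.scan_size
    k = np.round(fr / df).astype(np.intp).ravel()
    p = spec.ravel()
    sums = np.bincount(k, weights=p)
    counts = np.bincount(k)
    nbin = min(len(sums), n // 2 + 1)
    sel = counts[:nbin] > 0
    idx = np.arange(nbin)[sel]
    idx = idx[idx > 0]  # drop DC
    return idx * df, sums[idx] / counts[idx]


def estimate_hurst_periodogram(hmap: HeightMap) -> float:
    """Hurst exponent from the radially averaged periodogram slope.

    For a self-affine surface P(f) ~ f**-(2H+2); H is recovered from the
    log-log slope fitted between the 3rd radial bin and half the Nyquist
    frequency (avoiding the poorly populated lowest annuli and the
    aliased corner band).
    """
    freqs, power = radial_power_spectrum(hmap)
    nyq = 0.5 / hmap.pixel_size
    sel = (freqs >= freqs[2]) & (freqs <= 0.5 * nyq) & (power > 0)
    if sel.sum() < 4:
        raise DegenerateSurfaceError("too few spectral bins for a slope fit")
    slope, _ = _loglog_fit(freqs[sel], power[sel])
    return float((-slope - 2.0) / 2.0)
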