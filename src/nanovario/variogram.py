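"""Directional RMS-deviation maps, radial empirical variograms,
generalized q-moment variograms, and sill estimation.

For a square raster of z-values and an integer lag vector ``h = (v, p)``
(``v`` = x/column offset, ``p`` = y/row offset), the RMS deviation is

    D(v, p) = sqrt( (1/N) * sum [z(x_i, y_j) - z(x_i + v, y_j + p)]^2 )

over all in-bounds pairs, ``N = (n - |v|) * (n - |p|)``.  All four sign
quadrants of (v, p) are evaluated; since the pair set of ``(v, p)`` and
``(-v, -p)`` is identical, the map is exactly centrosymmetric.  The map
is computed with an FFT cross-correlation plus prefix-sum corner
rectangles, which reproduces the exhaustive all-pairs sum to floating
precision.

Radial (1D) variograms pool the squared differences of all lag vectors
whose magnitude ``|h| = sqrt(v^2 + p^2)`` falls in a bin, weighting by
pair count, giving the per-bin mean squared difference ``B(h)``.  The
generalized variogram of moment ``q`` is ``gamma(h, q) = B(h)^q``; at
``q = 0.5`` this is exactly the RMS deviation ``D(h)`` in the units of
z, and at ``q = 1`` the classical empirical variogram (mean squared
difference).  Note the per-lag identity ``gamma(h, q) = gamma(h, 1)^q``:
moments add discriminative power only through the nonlinear interaction
of the power transform with plateau averaging and group thresholds, not
through new per-lag information.

The *sill* is the plateau a variogram flattens to once lag vectors are
uncorrelated.  It is estimated as the pair-count-weighted mean of gamma
over the trailing fraction of the lag domain (default 30%), with a
slope-based quality flag when the curve is still rising there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft2, irfft2

from .errors import ParameterError
from .raster_io import HeightMap

__all__ = [
    "VariogramMap2D",
    "Variogram1D",
    "SillEstimate",
    "mean_square_deviation_map",
    "rms_deviation_map",
    "radial_variogram",
    "estimate_sill",
    "moment_sill_profile",
]


@dataclass
class VariogramMap2D:
    """RMS deviation D(h) on a signed lag grid (v, p) in [-L, L]^2.

    ``d_values[p + L, v + L]`` holds D(v, p); the center cell (zero lag)
    is zero by convention.  ``n_pairs`` holds N per lag.
    """

    d_values: np.ndarray
    n_pairs: np.ndarray
    max_lag_px: int
    pixel_size: float

    @property
    def lag_axis_px(self) -> np.ndarray:
        L = self.max_lag_px
        return np.arange(-L, L + 1)

    def d_at(self, v: int, p: int) -> float:
        """D at signed lag (v, p) in pixels."""
        L = self.max_lag_px
        if max(abs(v), abs(p)) > L:
            raise ParameterError(f"lag ({v}, {p}) outside computed range {L}")
        return float(self.d_values[p + L, v + L])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns v_px, p_px, lag_um, d, n_pairs."""
        L = self.max_lag_px
        vv, pp = np.meshgrid(self.lag_axis_px, self.lag_axis_px)
        return pd.DataFrame(
            {
                "v_px": vv.ravel(),
                "p_px": pp.ravel(),
                "lag_um": np.hypot(vv, pp).ravel() * self.pixel_size,
                "d": self.d_values.ravel(),
                "n_pairs": self.n_pairs.ravel(),
            }
        )


@dataclass
class Variogram1D:
    """Radially binned variogram curve for one moment q.

    ``gamma[i]`` is ``B_i^q`` where ``B_i`` is the pair-count-weighted
    mean squared difference of all lag vectors in bin i.  ``lag_um`` is
    the pair-weighted mean lag magnitude per bin, in micrometres.
    """

    lag_um: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    bin_edges_um: np.ndarray
    moment_q: float
    z_units: str = "um"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(self.gamma < 0):
            raise ParameterError("gamma must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.gamma)

    def with_moment(self, q: float) -> "Variogram1D":
        """Re-express this curve at another moment via gamma_q = B^q."""
        if not (q > 0):
            raise ParameterError(f"moment q must be > 0, got {q}")
        base = self.gamma ** (1.0 / self.moment_q)  # back to B
        return Variogram1D(
            lag_um=self.lag_um,
            gamma=base**q,
            pair_counts=self.pair_counts,
            bin_edges_um=self.bin_edges_um,
            moment_q=q,
            z_units=self.z_units,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_um": self.lag_um,
                "gamma": self.gamma,
                "n_pairs": self.pair_counts,
                "moment_q": self.moment_q,
            }
        )


@dataclass
class SillEstimate:
    """Plateau-mean sill of a 1D variogram.

    ``rising`` flags estimates where the curve's relative slope over the
    plateau window exceeds ``slope_cap`` (the variogram has not flattened
    off; the value is still returned).
    """

    sill_value: float
    plateau_range: tuple[float, float]
    method: str = "plateau_mean"
    rising: bool = False
    relative_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.sill_value < 0:
            raise ParameterError("sill must be non-negative")


def mean_square_deviation_map(values: np.ndarray, max_lag_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared difference B(v, p) and pair counts N(v, p).

    Returns ``(ms, n_pairs)`` on the ``(2L+1, 2L+1)`` signed-lag grid.
    Uses the identity sum[(a-b)^2] = sum[a^2] + sum[b^2] - 2*sum[a*b]:
    the cross term comes from one zero-padded FFT autocorrelation, the
    square sums from prefix-sum corner rectangles, so the result equals
    the exhaustive pair sum to floating precision.  The grand mean is
    subtracted first (B is invariant to constant offsets), which makes
    constant fields exactly zero.
    """
    z = np.asarray(values, dtype=np.float64)
    n = z.shape[0]
    L = int(max_lag_px)
    if not (1 <= L < n):
        raise ParameterError(f"max_lag_px must be in [1, {n - 1}], got {max_lag_px}")
    z = z - z.mean()

    # cross-correlation C(p, v) = sum_{j,i} z[j, i] * z[j+p, i+v]
    m = next_fast_len(2 * n - 1, real=True)
    F = rfft2(z, s=(m, m))
    corr = irfft2(F * np.conj(F), s=(m, m))
    idx = np.arange(-L, L + 1) % m
    C = corr[np.ix_(idx, idx)]

    # prefix sums of z^2 for corner-rectangle queries
    ps = np.zeros((n + 1, n + 1))
    ps[1:, 1:] = np.cumsum(np.cumsum(z * z, axis=0), axis=1)

    def rect(r0: np.ndarray, r1: np.ndarray, c0: np.ndarray, c1: np.ndarray) -> np.ndarray:
        return ps[r1, c1] - ps[r0, c1] - ps[r1, c0] + ps[r0, c0]

    lags = np.arange(-L, L + 1)
    pp, vv = np.meshgrid(lags, lags, indexing="ij")  # rows: p, cols: v
    row_lo = np.maximum(0, -pp)
    row_hi = n - np.maximum(0, pp)
    col_lo = np.maximum(0, -vv)
    col_hi = n - np.maximum(0, vv)
    s_base = rect(row_lo, row_hi, col_lo, col_hi)
    s_shift = rect(row_lo + pp, row_hi + pp, col_lo + vv, col_hi + vv)

    n_pairs = (n - np.abs(vv)) * (n - np.abs(pp))
    ms = (s_base + s_shift - 2.0 * C) / n_pairs
    np.clip(ms, 0.0, None, out=ms)
    ms[L, L] = 0.0
    # enforce exact centrosymmetry (the pair sets are identical)
    ms = 0.5 * (ms + ms[::-1, ::-1])
    return ms, n_pairs.astype(np.int64)


def rms_deviation_map(hmap: HeightMap, max_lag_px: int) -> VariogramMap2D:
    """Directional 2D RMS-deviation map D(v, p) of a (residual) field.

    Covers all four sign quadrants of the lag vector up to
    ``max(|v|, |p|) <= max_lag_px``; D is in the units of z.
    """
    ms, n_pairs = mean_square_deviation_map(hmap.values, max_lag_px)
    return VariogramMap2D(
        d_values=np.sqrt(ms),
        n_pairs=n_pairs,
        max_lag_px=int(max_lag_px),
        pixel_size=hmap.pixel_size,
    )


def default_max_lag(n_px: int) -> int:
    """Default maximum lag: n/4 px (keeps >= 75% pair overlap per lag)."""
    return max(1, n_px // 4)


def radial_variogram(
    hmap: HeightMap,
    max_lag_px: int | None = None,
    bin_width_px: float = 1.0,
    moment_q: float = 0.5,
) -> Variogram1D:
    """Radially binned variogram gamma(h, q) pooling all directions.

    Squared differences of every lag vector with ``0 < |h| <= max_lag_px``
    are pooled into bins of width ``bin_width_px`` by pair count, giving
    the per-bin mean squared difference B; the curve returned is B**q.
    Empty bins are excluded.  Lags are reported in micrometres.
    """
    if not (moment_q > 0):
        raise ParameterError(f"moment_q must be > 0, got {moment_q}")
    if not (bin_width_px > 0):
        raise ParameterError(f"bin_width_px must be > 0, got {bin_width_px}")
    n = hmap.n_px
    if max_lag_px is None:
        max_lag_px = default_max_lag(n)
    if not (1 <= max_lag_px < n):
        raise ParameterError(f"max_lag_px must be in [1, {n - 1}], got {max_lag_px}")

    L = int(np.ceil(max_lag_px))
    ms, n_pairs = mean_square_deviation_map(hmap.values, L)
    lags = np.arange(-L, L + 1)
    pp, vv = np.meshgrid(lags, lags, indexing="ij")
    mag = np.hypot(vv, pp)
    sel = (mag > 0) & (mag <= max_lag_px)

    mag_s = mag[sel]
    w = n_pairs[sel].astype(np.float64)
    b_vals = ms[sel]

    k = np.floor(mag_s / bin_width_px).astype(np.intp)
    n_bins = int(k.max()) + 1
    w_sum = np.bincount(k, weights=w, minlength=n_bins)
    b_sum = np.bincount(k, weights=w * b_vals, minlength=n_bins)
    lag_sum = np.bincount(k, weights=w * mag_s, minlength=n_bins)
    nonempty = w_sum > 0

    b_mean = b_sum[nonempty] / w_sum[nonempty]
    lag_mean_px = lag_sum[nonempty] / w_sum[nonempty]
    edges_px = np.arange(n_bins + 1) * bin_width_px

    return Variogram1D(
        lag_um=lag_mean_px * hmap.pixel_size,
        gamma=b_mean**moment_q,
        pair_counts=w_sum[nonempty],
        bin_edges_um=edges_px * hmap.pixel_size,
        moment_q=moment_q,
        z_units=hmap.value_units,
    )


def estimate_sill(
    vgram: Variogram1D,
    plateau_fraction: float = 0.3,
    slope_cap: float = 0.1,
) -> SillEstimate:
    """Plateau-mean sill over the trailing ``plateau_fraction`` of lags.

    The sill is the pair-count-weighted mean of gamma over the window
    ``[lag_max - f*(lag_max - lag_min), lag_max]``.  A linear fit over the
    window yields a relative slope (slope * window width / sill); if it
    exceeds ``slope_cap`` the estimate is flagged ``rising`` (variogram
    has not flattened off) but still returned.  Deterministic.
    """
    if not (0 < plateau_fraction < 1):
        raise ParameterError(f"plateau_fraction must be in (0, 1), got {plateau_fraction}")
    if vgram.n_bins < 5:
        raise ParameterError(
            f"need >= 5 non-empty bins for a sill estimate, got {vgram.n_bins}"
        )
    lag = vgram.lag_um
    lo = lag[-1] - plateau_fraction * (lag[-1] - lag[0])
    sel = lag >= lo
    if sel.sum() < 2:
        sel = np.zeros_like(sel)
        sel[-2:] = True
    g = vgram.gamma[sel]
    w = vgram.pair_counts[sel]
    x = lag[sel]
    sill = float(np.sum(w * g) / np.sum(w))

    rising = False
    rel_slope = 0.0
    if x[-1] > x[0] and sill > 0:
        slope = np.polyfit(x, g, 1)[0]
        rel_slope = float(slope * (x[-1] - x[0]) / sill)
        rising = abs(rel_slope) > slope_cap
    return SillEstimate(
        sill_value=sill,
        plateau_range=(float(x[0]), float(x[-1])),
        rising=rising,
        relative_slope=rel_slope,
    )


def moment_sill_profile(
    hmap: HeightMap,
    q_list: list[float] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0),
    max_lag_px: int | None = None,
    bin_width_px: float = 1.0,
    plateau_fraction: float = 0.3,
) -> list[tuple[float, SillEstimate]]:
    """One sill per moment q, all from the same binned B(h).

    The binned mean squared difference B is computed once; for each q the
    curve ``B**q`` is formed and its plateau-mean sill estimated.  Sills
    are monotone in q wherever the plateau B exceeds 1 in working units
    (and anti-monotone below 1): the q-profile is unit-dependent, so
    compare sills across samples only at matched q and units.
    """
    for q in q_list:
        if not (q > 0):
            raise ParameterError(f"all moments must be > 0, got {q}")
    base = radial_variogram(hmap, max_lag_px=max_lag_px, bin_width_px=bin_width_px, moment_q=1.0)
    out = []
    for q in q_list:
        vg_q = base.with_moment(q)
        out.append((q, estimate_sill(vg_q, plateau_fraction=plateau_fraction)))
    return out
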