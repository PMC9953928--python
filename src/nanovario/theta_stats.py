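"""Facet-inclination ("theta") statistics of a height field.

Each interior pixel defines a tiny planar facet whose inclination against
the horizontal plane is ``theta = arctan(|grad z|)`` in degrees, with the
gradient from central differences scaled by the physical pixel size (z
and lateral spacing both in micrometres).  The theta histogram over
[0, 90] degrees and the skewness / excess kurtosis of the *raw* facet
angles (not the binned histogram) are texture markers: broad, low-angle
distributions indicate smoother, de-oriented surfaces, sharp high-angle
peaks indicate regular fine structure.

Theta is invariant to adding a constant to z and equivariant under
z-rescaling (z -> k*z maps theta -> arctan(k*tan(theta))).

The facet is the smallest planar segment the grid supports: a 1-pixel
neighbourhood with central-difference normal.  An optional k x k
least-squares plane-fit facet is available for coarser facets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .raster_io import HeightMap

__all__ = ["ThetaDistribution", "facet_angles", "theta_distribution"]


@dataclass
class ThetaDistribution:
    """Normalized histogram of facet inclination angles plus moments.

    ``density`` integrates to 1 over the bin edges (degrees).  Skewness
    and kurtosis (Fisher/excess convention, normal = 0) are computed from
    the raw angle sample.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    skewness: float
    kurtosis: float
    n_facets: int

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"theta_deg": centers, "density": self.density})


def facet_angles(hmap: HeightMap, facet_px: int = 1) -> np.ndarray:
    """Inclination angle (degrees) of each interior facet.

    ``facet_px = 1`` (default) uses per-pixel central differences;
    ``facet_px = k > 1`` fits a least-squares plane to each k x k block
    and returns its inclination.  Boundary pixels are excluded.
    """
    n = hmap.n_px
    if n < 3:
        raise ParameterError("need at least a 3x3 raster for facet angles")
    z = hmap.values
    px = hmap.pixel_size
    if facet_px == 1:
        gx = (z[1:-1, 2:] - z[1:-1, :-2]) / (2.0 * px)
        gy = (z[2:, 1:-1] - z[:-2, 1:-1]) / (2.0 * px)
        grad = np.hypot(gx, gy)
        return np.degrees(np.arctan(grad)).ravel()
    if facet_px < 1 or facet_px > n:
        raise ParameterError(f"facet_px must be in [1, {n}], got {facet_px}")
    k = facet_px
    m = n // k
    blocks = z[: m * k, : m * k].reshape(m, k, m, k).transpose(0, 2, 1, 3)
    # least-squares plane slope over a k x k block: regress z on x and y
    coords = (np.arange(k) - (k - 1) / 2.0) * px
    denom = k * np.sum(coords**2)
    gx = np.einsum("abij,j->ab", blocks, coords) / denom
    gy = np.einsum("abij,i->ab", blocks, coords) / denom
    grad = np.hypot(gx, gy)
    return np.degrees(np.arctan(grad)).ravel()


def theta_distribution(
    hmap: HeightMap, bin_width_deg: float = 1.0, facet_px: int = 1
) -> ThetaDistribution:
    """Histogram of facet angles over [0, 90] degrees plus raw moments."""
    if not (0 < bin_width_deg <= 10):
        raise ParameterError(
            f"bin_width_deg must be in (0, 10], got {bin_width_deg}"
        )
    angles = facet_angles(hmap, facet_px=facet_px)
    if angles.size < 10:
        raise ParameterError(f"need >= 10 facets, got {angles.size}")
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    if edges[-1] < 90.0:
        edges = np.append(edges, 90.0)
    density, edges = np.histogram(angles, bins=edges, density=True)
    return ThetaDistribution(
        bin_edges=edges,
        density=density,
        skewness=float(stats.skew(angles)),
        kurtosis=float(stats.kurtosis(angles)),  # excess (Fisher)
        n_facets=int(angles.size),
    )
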