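"""Gaussian smoothing and high-pass residual of a height field.

The roughness signal all variogram analysis consumes is the *residual* of
a Gaussian low-pass filter: ``residual = original - smoothed``.  The
residual is a high-pass field that keeps structure at spatial scales
smaller than the kernel box (the cut-off box is ``6*sigma + 1`` pixels,
about 3 um for sigma = 5 px at 97.7 nm/px), with some leakage.

The filter is a 2D spatial Gaussian applied to the scalar z-field with
the same sigma along both image axes.  (AFM vendors sometimes call this a
"3D" or "cubic" filter because it acts on a 3D surface plot; over a 2D
raster only the two lateral dimensions are filterable.)  The kernel is
truncated exactly at the ``6*sigma + 1`` box — not at library-default
tails — so sigma = 5 px gives a 31-px kernel; ties in "nearest odd"
round up.  Kernel weights are normalized to sum to one, so constant
fields are fixed points and the residual has no DC component.

No plane/line levelling or background subtraction is applied: the
Gaussian residual itself removes large-scale relief.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .raster_io import HeightMap

__all__ = ["FilterSpec", "gaussian_kernel_1d", "gaussian_smooth", "gaussian_residual"]

_BOUNDARY_MODES = ("reflect", "nearest", "wrap")


@dataclass(frozen=True)
class FilterSpec:
    """Gaussian filter settings.

    ``sigma_px`` is the standard deviation in pixels; the kernel box is
    derived, never set directly.  ``boundary`` selects edge handling
    (default ``reflect``, which avoids edge-ramp artifacts that would
    inflate residual sills).
    """

    sigma_px: float
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if not (self.sigma_px > 0):
            raise ParameterError(f"sigma_px must be > 0, got {self.sigma_px}")
        if self.boundary not in _BOUNDARY_MODES:
            raise ParameterError(
                f"boundary must be one of {_BOUNDARY_MODES}, got {self.boundary!r}"
            )

    @property
    def kernel_size_px(self) -> int:
        """Kernel box: nearest odd integer to ``6*sigma + 1`` (ties up)."""
        return 2 * int(np.floor(3.0 * self.sigma_px + 0.5)) + 1

    def sigma_um(self, pixel_size: float) -> float:
        """Standard deviation in micrometres for a given pixel size."""
        return self.sigma_px * pixel_size

    @classmethod
    def from_um(cls, sigma_um: float, pixel_size: float, boundary: str = "reflect") -> "FilterSpec":
        """Build a spec from a physical sigma and the raster's pixel size."""
        if not (pixel_size > 0):
            raise ParameterError("pixel_size must be > 0")
        return cls(sigma_px=sigma_um / pixel_size, boundary=boundary)


def gaussian_kernel_1d(spec: FilterSpec) -> np.ndarray:
    """Normalized 1D Gaussian kernel truncated at the ``6*sigma+1`` box."""
    r = (spec.kernel_size_px - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    w = np.exp(-0.5 * (x / spec.sigma_px) ** 2)
    return w / w.sum()


def gaussian_smooth(hmap: HeightMap, spec: FilterSpec) -> HeightMap:
    """Separable Gaussian convolution of the z-values.

    Output has the same shape and metadata.  Raises if the kernel box
    exceeds the image.
    """
    k = spec.kernel_size_px
    if k > hmap.n_px:
        raise ParameterError(
            f"kernel box {k} px exceeds image size {hmap.n_px} px"
        )
    w = gaussian_kernel_1d(spec)
    sm = ndimage.convolve1d(hmap.values, w, axis=0, mode=spec.boundary)
    sm = ndimage.convolve1d(sm, w, axis=1, mode=spec.boundary)
    return hmap.with_values(sm)


def gaussian_residual(hmap: HeightMap, spec: FilterSpec) -> HeightMap:
    """High-pass residual: ``original - gaussian_smooth(original)``.

    Elementwise, so ``smoothed + residual == original`` to floating
    tolerance.  Constant maps give an all-zero residual.
    """
    smoothed = gaussian_smooth(hmap, spec)
    return hmap.with_values(hmap.values - smoothed.values)
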