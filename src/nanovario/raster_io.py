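"""Height-map container and raster I/O.

AFM images are square rasters of z-values (height, amplitude or phase
channel) with a physical scan size.  The on-disk formats are deliberately
simple and text-first: a whitespace-delimited matrix (``.txt``) or a
grayscale float TIFF (``.tif``/``.tiff``), each accompanied by a YAML
sidecar carrying the physical metadata (scan size in micrometres, channel,
value units).  This mirrors the Gwyddion-style ASCII export that is the
lingua franca for scanning-probe data; vendor binary formats are out of
scope.

Coordinate convention (fixed so that lag-vector quadrants are
reproducible): arrays are row-major with the origin at the top-left,
``x`` = column index, ``y`` = row index, both 0-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import MetadataError, ParameterError, RasterFormatError

__all__ = [
    "HeightMap",
    "read_raster",
    "write_raster",
    "downsample",
    "read_manifest",
    "write_manifest",
]

CHANNELS = ("height", "amplitude", "phase")

#: default value units per channel
_DEFAULT_UNITS = {"height": "um", "amplitude": "um", "phase": "deg"}


@dataclass
class HeightMap:
    """A square raster of z-values with physical pixel size.

    Parameters
    ----------
    values
        ``(n, n)`` array of finite z-values.  Stored as float64.
    pixel_size
        Physical size of one pixel in micrometres (``scan_size / n``).
    channel
        One of ``height``, ``amplitude``, ``phase``.
    value_units
        Units of the z-values: micrometres for height/amplitude,
        degrees for phase.
    sample_id
        Free-form identifier (e.g. ``m1.2`` / ``nm2.4``).
    """

    values: np.ndarray
    pixel_size: float
    channel: str = "height"
    value_units: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise RasterFormatError(
                f"raster must be a square 2D grid, got shape {self.values.shape}"
            )
        if self.values.size < 1:
            raise RasterFormatError("raster must not be empty")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise RasterFormatError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if not (self.pixel_size > 0):
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.channel not in CHANNELS:
            raise ParameterError(
                f"channel must be one of {CHANNELS}, got {self.channel!r}"
            )
        if not self.value_units:
            self.value_units = _DEFAULT_UNITS[self.channel]

    @property
    def n_px(self) -> int:
        """Number of points per axis."""
        return self.values.shape[0]

    @property
    def scan_size(self) -> float:
        """Physical edge length of the scan in micrometres."""
        return self.n_px * self.pixel_size

    def with_values(self, values: np.ndarray) -> "HeightMap":
        """Copy of this map with new z-values and identical metadata."""
        return replace(self, values=np.asarray(values, dtype=np.float64))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_raster(hmap: HeightMap, path: str | Path) -> None:
    """Write a HeightMap to ``path`` with a YAML metadata sidecar.

    ``.txt`` writes a whitespace-delimited matrix at full float64
    precision; ``.tif``/``.tiff`` writes a float64 grayscale TIFF.  Either
    way the sidecar (same stem, ``.yaml``) records scan size, channel,
    units and sample id, so ``read_raster(write_raster(m))`` round-trips
    bit-exactly.
    """
    path = Path(path)
    meta = {
        "n_px": int(hmap.n_px),
        "scan_size_um": float(hmap.scan_size),
        "channel": hmap.channel,
        "value_units": hmap.value_units,
        "sample_id": hmap.sample_id,
    }
    if path.suffix == ".txt":
        np.savetxt(path, hmap.values, fmt="%.17g")
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, hmap.values)
    else:
        raise ParameterError(f"unsupported raster extension {path.suffix!r}")
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_raster(
    path: str | Path,
    scan_size_um: float | None = None,
    channel: str | None = None,
    value_units: str | None = None,
    sample_id: str | None = None,
) -> HeightMap:
    """Read a raster plus its metadata.

    Metadata is taken from the YAML sidecar (same stem, ``.yaml``) when
    present; keyword arguments override sidecar values.  The scan size is
    mandatory (pixel size is ``scan_size / n``), the channel defaults to
    ``height``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    if scan_size_um is not None:
        meta["scan_size_um"] = scan_size_um
    if channel is not None:
        meta["channel"] = channel
    if value_units is not None:
        meta["value_units"] = value_units
    if sample_id is not None:
        meta["sample_id"] = sample_id

    if path.suffix == ".txt":
        values = np.loadtxt(path, ndmin=2)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=np.float64)
    else:
        raise ParameterError(f"unsupported raster extension {path.suffix!r}")

    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise RasterFormatError(
            f"{path}: raster must be square, got shape {values.shape}"
        )
    if "scan_size_um" not in meta:
        raise MetadataError(
            f"{path}: scan size missing — provide a sidecar or scan_size_um"
        )
    n = values.shape[0]
    return HeightMap(
        values=values,
        pixel_size=float(meta["scan_size_um"]) / n,
        channel=meta.get("channel", "height"),
        value_units=meta.get("value_units", ""),
        sample_id=meta.get("sample_id", ""),
    )


def downsample(hmap: HeightMap, target_n: int) -> HeightMap:
    """Block-mean decimation to ``target_n`` points per axis.

    ``target_n`` must divide ``n``.  The physical scan size is preserved,
    so the pixel size scales by ``n / target_n``.  Block means average to
    the global mean, hence the grid mean is preserved exactly.
    """
    n = hmap.n_px
    if not (1 <= target_n <= n):
        raise ParameterError(f"target_n must be in [1, {n}], got {target_n}")
    if n % target_n != 0:
        raise ParameterError(f"target_n={target_n} does not divide n={n}")
    b = n // target_n
    blocks = hmap.values.reshape(target_n, b, target_n, b)
    return HeightMap(
        values=blocks.mean(axis=(1, 3)),
        pixel_size=hmap.pixel_size * b,
        channel=hmap.channel,
        value_units=hmap.value_units,
        sample_id=hmap.sample_id,
    )


def write_manifest(rows: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write a cohort manifest CSV with columns sample_id, label, path."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label", "path"])
        writer.writerows(rows)


def read_manifest(path: str | Path) -> list[dict]:
    """Read a cohort manifest CSV into a list of row dicts."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
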