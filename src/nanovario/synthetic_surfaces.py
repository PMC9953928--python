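"""Synthetic AFM-like surfaces: analytic fixtures, fractional Brownian
surfaces of known Hurst exponent, and two-class tissue phantoms.

The phantoms emulate the second-order texture contrast between two tissue
classes observed on histological AFM scans: a rougher, fine-structured
class (non-metastatic-like, higher Gaussian-residual variogram sill) and
a smoother class (metastatic-like, lower sill).  Both classes share the
same large-scale relief statistics — an offset, long-correlation-length
random landscape — and differ only in the RMS of a band-limited speckle
texture living at sub-micrometre scales, i.e. exactly in the band a
Gaussian high-pass residual isolates.  The class contrast is a fixed
factor of 2 in fine-texture RMS (a factor 4 in residual variance), which
qualitatively reproduces the reported ordering of residual RMS deviations
(~0.17 um for the smoother vs ~0.27 um for the rougher class).

The speckle texture is white noise smoothed to a correlation length of a
few hundred nanometres rather than raw per-pixel noise: per-pixel noise
would not survive block-mean decimation, whereas physical sub-micrometre
texture must yield resolution-invariant sills when sigma is held fixed in
micrometres.  No attempt is made to model actual cell morphology, nuclei
or ECM fibres.

Fractional Brownian surfaces are synthesized spectrally (Fourier
synthesis with the Hermitian symmetry a real field implies) with power
spectral density proportional to f**-(2H+2), so spectral estimators have
a known ground truth and D_f = 3 - H.

All generators are seed-deterministic: an identical SurfaceSpec
(including seed) reproduces a bit-identical surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .raster_io import HeightMap

__all__ = ["SurfaceSpec", "generate_surface", "generate_cohort", "SMOOTH_CONTRAST"]

KINDS = (
    "constant",
    "plane",
    "sine",
    "white_noise",
    "fbm",
    "phantom_rough",
    "phantom_smooth",
)

#: factor by which the smooth (metastatic-like) class's fine-texture RMS
#: is reduced relative to the rough (non-metastatic-like) class
SMOOTH_CONTRAST = 2.0

#: lognormal sigma of the per-sample fine-texture RMS jitter in cohorts
COHORT_RMS_JITTER = 0.12


@dataclass(frozen=True)
class SurfaceSpec:
    """Recipe for one synthetic surface.

    Parameters
    ----------
    kind
        One of ``constant``, ``plane``, ``sine``, ``white_noise``,
        ``fbm``, ``phantom_rough``, ``phantom_smooth``.
    n_px
        Points per axis (>= 8).
    scan_size
        Physical edge length in micrometres.
    amplitude
        Scale of the surface in micrometres: the constant value
        (constant), total rise across the image (plane), sine amplitude,
        white-noise standard deviation, fBm RMS, or relief RMS (phantoms).
    hurst
        Hurst exponent in (0, 1); fBm only.
    fine_texture_rms
        RMS (um) of the sub-micrometre speckle texture; phantoms only.
        ``phantom_smooth`` divides this by ``SMOOTH_CONTRAST``.
    texture_corr_um
        Speckle correlation length (Gaussian sigma, um); phantoms only.
    relief_corr_um
        Large-scale relief correlation length (um); phantoms only.
    wavelength_px
        Ridge wavelength in pixels; sine only.
    seed
        RNG seed (determinism contract).
    """

    kind: str
    n_px: int = 512
    scan_size: float = 50.0
    amplitude: float = 0.8
    hurst: float | None = None
    fine_texture_rms: float | None = 0.19
    texture_corr_um: float = 0.35
    relief_corr_um: float = 10.0
    wavelength_px: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.n_px < 8:
            raise ParameterError(f"n_px must be >= 8, got {self.n_px}")
        if not (self.scan_size > 0):
            raise ParameterError(f"scan_size must be > 0, got {self.scan_size}")
        if self.amplitude < 0:
            raise ParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.kind == "fbm":
            if self.hurst is None or not (0 < self.hurst < 1):
                raise ParameterError(
                    f"hurst must be in (0, 1) for fbm, got {self.hurst}"
                )
        if self.kind.startswith("phantom"):
            if self.fine_texture_rms is None or not (self.fine_texture_rms > 0):
                raise ParameterError(
                    f"fine_texture_rms must be > 0 for phantoms, got {self.fine_texture_rms}"
                )
            if not (self.texture_corr_um > 0) or not (self.relief_corr_um > 0):
                raise ParameterError("correlation lengths must be > 0")
        if self.kind == "sine" and not (self.wavelength_px > 0):
            raise ParameterError(f"wavelength_px must be > 0, got {self.wavelength_px}")

    @property
    def pixel_size(self) -> float:
        return self.scan_size / self.n_px


def _rng(seed_key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_key))


def _fbm_field(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Spectral fBm synthesis: filter white noise to PSD ~ f**-(2H+2).

    Filtering the FFT of a real white-noise field by a radially symmetric
    real gain preserves Hermitian symmetry, so the inverse transform is
    real up to rounding.
    """
    noise = rng.standard_normal((n, n))
    f1d = np.fft.fftfreq(n)
    fx, fy = np.meshgrid(f1d, f1d)
    fr = np.hypot(fx, fy)
    with np.errstate(divide="ignore"):
        gain = np.where(fr > 0, fr ** -(hurst + 1.0), 0.0)
    field = np.fft.ifft2(np.fft.fft2(noise) * gain).real
    return field


def _smoothed_noise(n: int, sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-RMS Gaussian-correlated noise (wrap boundary)."""
    w = rng.standard_normal((n, n))
    sm = ndimage.gaussian_filter(w, sigma=sigma_px, mode="wrap")
    sm -= sm.mean()
    rms = sm.std()
    if rms == 0:
        raise ParameterError("degenerate smoothed-noise field")
    return sm / rms


def _phantom(spec: SurfaceSpec) -> np.ndarray:
    n = spec.n_px
    px = spec.pixel_size
    # relief and texture come from independent substreams of the same
    # seed, so rough/smooth phantoms at one seed share the relief exactly
    relief_rng = _rng((spec.seed, 0))
    texture_rng = _rng((spec.seed, 1))

    relief_sigma_px = spec.relief_corr_um / px
    relief = _smoothed_noise(n, relief_sigma_px, relief_rng) * spec.amplitude
    offset = 2.5 * spec.amplitude  # keeps z positive, like real AFM heights

    rms = spec.fine_texture_rms
    if spec.kind == "phantom_smooth":
        rms = rms / SMOOTH_CONTRAST
    texture_sigma_px = spec.texture_corr_um / px
    texture = _smoothed_noise(n, texture_sigma_px, texture_rng) * rms
    return offset + relief + texture


def generate_surface(spec: SurfaceSpec) -> HeightMap:
    """Generate the surface a SurfaceSpec describes.

    Deterministic in the spec (including seed).  The returned HeightMap
    has ``pixel_size = scan_size / n_px`` and channel ``height``.
    """
    n = spec.n_px
    if spec.kind == "constant":
        z = np.full((n, n), spec.amplitude)
    elif spec.kind == "plane":
        # z = a * x with per-pixel slope a = amplitude / (n - 1), exactly
        col = np.arange(n, dtype=np.float64)
        z = np.broadcast_to(col * (spec.amplitude / (n - 1)), (n, n)).copy()
    elif spec.kind == "sine":
        col = np.arange(n, dtype=np.float64)
        row = spec.amplitude * np.sin(2.0 * np.pi * col / spec.wavelength_px)
        z = np.broadcast_to(row, (n, n)).copy()
    elif spec.kind == "white_noise":
        z = _rng((spec.seed,)).standard_normal((n, n)) * spec.amplitude
    elif spec.kind == "fbm":
        field = _fbm_field(n, spec.hurst, _rng((spec.seed,)))
        field -= field.mean()
        rms = field.std()
        z = field * (spec.amplitude / rms) if rms > 0 else field
    else:
        z = _phantom(spec)
    return HeightMap(values=z, pixel_size=spec.pixel_size, channel="height")


def generate_cohort(
    n_met: int,
    n_nonmet: int,
    base_spec: SurfaceSpec | None = None,
    seed: int = 0,
) -> list[tuple[str, str, HeightMap]]:
    """Two-class phantom cohort with m{i}.{j} / nm{i}.{j} sample ids.

    Metastatic-labelled samples use ``phantom_smooth``, non-metastatic
    ``phantom_rough``.  Sample ids follow the patient.section convention:
    metastatic samples are spread over 3 synthetic patients and
    non-metastatic over 2 (the 18-section, 5-patient layout of a typical
    study cohort).  Each sample gets its own relief/texture seed and a
    lognormal jitter (sigma = 0.12) on the fine-texture RMS so groups
    have realistic within-class dispersion.  Deterministic for a fixed
    seed.
    """
    if n_met < 1 or n_nonmet < 1:
        raise ParameterError("need at least one sample per class")
    if base_spec is None:
        base_spec = SurfaceSpec(kind="phantom_rough")
    out: list[tuple[str, str, HeightMap]] = []
    jitter_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))

    def build(kind: str, label: str, count: int, n_patients: int, prefix: str, offset: int):
        counters = [0] * n_patients
        for i in range(count):
            patient = i % n_patients
            counters[patient] += 1
            sid = f"{prefix}{patient + 1}.{counters[patient]}"
            sample_seed = int(
                np.random.SeedSequence((seed, 2, offset + i)).generate_state(1)[0] % (2**31)
            )
            rms = base_spec.fine_texture_rms * float(
                np.exp(jitter_rng.normal(0.0, COHORT_RMS_JITTER))
            )
            spec = replace(
                base_spec, kind=kind, fine_texture_rms=rms, seed=sample_seed
            )
            hm = generate_surface(spec)
            hm.sample_id = sid
            out.append((sid, label, hm))

    build("phantom_smooth", "metastatic", n_met, 3, "m", 0)
    build("phantom_rough", "non_metastatic", n_nonmet, 2, "nm", n_met)
    return out
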