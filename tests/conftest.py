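"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nanovario import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_random_map(rng):
    """A 16x16 random height map, 1 um pixels."""
    return HeightMap(values=rng.normal(size=(16, 16)), pixel_size=1.0)


def brute_force_msd(z: np.ndarray, v: int, p: int) -> tuple[float, int]:
    """Exhaustive all-pairs mean squared difference at signed lag (v, p).

    Double loop over every in-bounds pair; the independent oracle for the
    FFT-based deviation map.
    """
    n = z.shape[0]
    acc = 0.0
    count = 0
    for j in range(n):
        for i in range(n):
            jj, ii = j + p, i + v
            if 0 <= jj < n and 0 <= ii < n:
                acc += (z[j, i] - z[jj, ii]) ** 2
                count += 1
    return acc / count, count


def fgn_series(length: int, hurst: float, seed: int) -> np.ndarray:
    """Fractional Gaussian noise by 1D spectral synthesis + differencing.

    Builds a 1D profile with power spectrum f**-(2H+1) and returns its
    increments (a stationary series with Hurst exponent H).
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(length + 1)
    f = np.fft.rfftfreq(length + 1)
    with np.errstate(divide="ignore"):
        gain = np.where(f > 0, f ** -(hurst + 0.5), 0.0)
    profile = np.fft.irfft(np.fft.rfft(noise) * gain, length + 1)
    return np.diff(profile)
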