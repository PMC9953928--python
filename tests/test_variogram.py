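"""Deviation maps, radial variograms, moment curves and sill estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_msd
from nanovario import (
    HeightMap,
    ParameterError,
    Variogram1D,
    estimate_sill,
    moment_sill_profile,
    radial_variogram,
    rms_deviation_map,
)


def plane_map(n: int, slope: float, pixel_size: float = 1.0) -> HeightMap:
    z = slope * np.arange(n)[None, :] * np.ones((n, 1))
    return HeightMap(z.copy(), pixel_size)


class TestRmsDeviationMap:
    @pytest.mark.parametrize("n,max_lag", [(6, 2), (12, 5), (32, 8)])
    def test_equals_brute_force_all_pairs_oracle(self, n, max_lag):
        z = np.random.default_rng(n).integers(0, 10, (n, n)).astype(float)
        vmap = rms_deviation_map(HeightMap(z, 1.0), max_lag)
        for p in range(-max_lag, max_lag + 1):
            for v in range(-max_lag, max_lag + 1):
                if v == 0 and p == 0:
                    continue
                msd, count = brute_force_msd(z, v, p)
                assert vmap.d_at(v, p) == pytest.approx(np.sqrt(msd), rel=1e-12)
                L = vmap.max_lag_px
                assert vmap.n_pairs[p + L, v + L] == count

    def test_pair_count_formula(self):
        z = np.random.default_rng(1).normal(size=(10, 10))
        vmap = rms_deviation_map(HeightMap(z, 1.0), 3)
        for p in range(-3, 4):
            for v in range(-3, 4):
                assert vmap.n_pairs[p + 3, v + 3] == (10 - abs(v)) * (10 - abs(p))

    def test_centrosymmetry_exact(self, small_random_map):
        vmap = rms_deviation_map(small_random_map, 5)
        np.testing.assert_array_equal(vmap.d_values, vmap.d_values[::-1, ::-1])

    def test_constant_field_gives_zero(self):
        vmap = rms_deviation_map(HeightMap(np.full((16, 16), 0.3), 1.0), 4)
        np.testing.assert_allclose(vmap.d_values, 0.0, atol=1e-12)

    def test_plane_gives_abs_a_v_for_all_p(self):
        a = 0.25
        vmap = rms_deviation_map(plane_map(24, a), 6)
        for p in range(-6, 7):
            for v in range(-6, 7):
                if v == 0 and p == 0:
                    continue
                # sqrt of an eps-level mean square leaves ~1e-8 noise
                assert vmap.d_at(v, p) == pytest.approx(abs(a * v), abs=1e-6)

    def test_max_lag_bounds(self, small_random_map):
        with pytest.raises(ParameterError):
            rms_deviation_map(small_random_map, 16)
        with pytest.raises(ParameterError):
            rms_deviation_map(small_random_map, 0)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegative_and_centrosymmetric_on_random_maps(self, seed):
        z = np.random.default_rng(seed).normal(size=(12, 12))
        vmap = rms_deviation_map(HeightMap(z, 1.0), 4)
        assert np.all(vmap.d_values >= 0)
        np.testing.assert_array_equal(vmap.d_values, vmap.d_values[::-1, ::-1])
        assert vmap.d_values[4, 4] == 0.0


class TestRadialVariogram:
    def test_white_noise_curve_is_flat_at_sqrt2_sigma(self):
        # E[(z1 - z2)^2] = 2 s^2 for iid noise, so D = s*sqrt(2) at every lag
        for seed in range(10):
            z = np.random.default_rng(seed).standard_normal((128, 128))
            vg = radial_variogram(HeightMap(z, 1.0), moment_q=0.5)
            np.testing.assert_allclose(vg.gamma, np.sqrt(2), rtol=0.05)

    def test_power_identity_gamma_q2_equals_gamma_q1_squared(self, small_random_map):
        g1 = radial_variogram(small_random_map, max_lag_px=6, moment_q=1.0)
        g2 = radial_variogram(small_random_map, max_lag_px=6, moment_q=2.0)
        np.testing.assert_allclose(g2.gamma, g1.gamma**2, rtol=1e-12)

    def test_plane_variogram_grows_without_flattening(self):
        vg = radial_variogram(plane_map(64, 0.5), max_lag_px=16, moment_q=0.5)
        # drift: strictly increasing overall and never flattens -> rising flag
        assert vg.gamma[-1] > vg.gamma[0]
        est = estimate_sill(vg)
        assert est.rising

    def test_lags_reported_in_um(self):
        z = np.random.default_rng(3).normal(size=(32, 32))
        vg = radial_variogram(HeightMap(z, 0.5), max_lag_px=8)
        # first bin pools |h| in [1, 2) px -> weighted mean in [0.5, 1.0) um
        assert 0.5 <= vg.lag_um[0] < 1.0
        assert vg.lag_um[-1] <= 8 * 0.5

    def test_invalid_moment_raises(self, small_random_map):
        with pytest.raises(ParameterError):
            radial_variogram(small_random_map, moment_q=0.0)


class TestEstimateSill:
    @staticmethod
    def synthetic_vgram(gamma, lags=None, q=0.5):
        gamma = np.asarray(gamma, dtype=float)
        n = len(gamma)
        lags = np.arange(1.0, n + 1) if lags is None else np.asarray(lags)
        return Variogram1D(
            lag_um=lags,
            gamma=gamma,
            pair_counts=np.full(n, 100.0),
            bin_edges_um=np.arange(n + 1, dtype=float),
            moment_q=q,
        )

    def test_constant_curve_returns_constant(self):
        for frac in (0.2, 0.3, 0.5):
            vg = self.synthetic_vgram(np.full(20, 0.7))
            assert estimate_sill(vg, plateau_fraction=frac).sill_value == pytest.approx(0.7)

    def test_exponential_model_recovers_sill_within_2pct(self):
        # gamma(h) = c (1 - exp(-h/r)) with r << lag_max flattens to c
        c, r = 2.0, 1.5
        lags = np.arange(1.0, 41.0)
        vg = self.synthetic_vgram(c * (1 - np.exp(-lags / r)), lags=lags)
        est = estimate_sill(vg, plateau_fraction=0.3)
        assert est.sill_value == pytest.approx(c, rel=0.02)
        assert not est.rising

    def test_white_noise_sill_is_sqrt2(self):
        sills = []
        for seed in range(10):
            z = np.random.default_rng(seed).standard_normal((128, 128))
            vg = radial_variogram(HeightMap(z, 1.0), moment_q=0.5)
            sills.append(estimate_sill(vg).sill_value)
        assert np.mean(sills) == pytest.approx(np.sqrt(2), rel=0.03)

    def test_too_few_bins_raises(self):
        vg = self.synthetic_vgram(np.ones(4))
        with pytest.raises(ParameterError, match="bins"):
            estimate_sill(vg)

    def test_plateau_range_recorded_within_domain(self):
        vg = self.synthetic_vgram(np.full(20, 1.0))
        est = estimate_sill(vg, plateau_fraction=0.3)
        lo, hi = est.plateau_range
        assert vg.lag_um[0] <= lo < hi <= vg.lag_um[-1]


class TestMomentSillProfile:
    def test_six_moments_finite_nonnegative(self, small_random_map):
        profile = moment_sill_profile(small_random_map, q_list=[0.5, 1, 2, 3, 4, 5], max_lag_px=6)
        assert len(profile) == 6
        for q, est in profile:
            assert np.isfinite(est.sill_value)
            assert est.sill_value >= 0

    def test_power_identity_of_sills_within_plateau_tolerance(self):
        z = np.random.default_rng(7).standard_normal((64, 64))
        profile = dict(moment_sill_profile(HeightMap(z, 1.0), q_list=[0.5, 1.0]))
        # multi-bin plateau: equality holds to plateau-averaging tolerance
        assert profile[1.0].sill_value == pytest.approx(profile[0.5].sill_value ** 2, rel=0.01)

    def test_relative_separation_grows_with_q_for_distinct_plateaus(self):
        # two flat variograms with B-plateaus 0.25 and 0.36: the sill gap
        # relative to the smaller sill widens as the moment grows
        b1, b2 = 0.25, 0.36
        for q_lo, q_hi in [(0.5, 5.0), (1.0, 3.0)]:
            rel_lo = (b2**q_lo - b1**q_lo) / b1**q_lo
            rel_hi = (b2**q_hi - b1**q_hi) / b1**q_hi
            assert rel_hi > rel_lo

    def test_invalid_q_raises(self, small_random_map):
        with pytest.raises(ParameterError):
            moment_sill_profile(small_random_map, q_list=[1.0, -2.0], max_lag_px=6)
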