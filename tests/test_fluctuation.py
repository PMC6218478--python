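"""Relative-rate cross-correlation of intensity and height fluctuations."""

import numpy as np
import pytest

from epifold.fluctuation import (
    cross_correlation,
    min_lag,
    null_bound,
    relative_rate,
)
from epifold.synthetic import gen_coupled_timeseries


def pipeline(series, max_lag=100.0):
    dt = series[0].dt
    g1 = [relative_rate(s.a_l, dt) for s in series]
    g2 = [relative_rate(s.h, dt) for s in series]
    return g1, g2, cross_correlation(g1, g2, max_lag=max_lag, dt=dt)


class TestRelativeRate:
    def test_constant_series_has_zero_rate(self):
        assert np.allclose(relative_rate(np.full(10, 3.7)), 0.0)

    def test_linear_series_value(self):
        # x = 1 + t with dt = 1: g at x_i = 2 equals 1/2
        x = 1.0 + np.arange(5.0)
        g = relative_rate(x, dt=1.0)
        assert g[0] == pytest.approx(0.5)

    def test_exponential_closed_form(self):
        lam, dt = 0.3, 0.05
        t = np.arange(50) * dt
        g = relative_rate(np.exp(lam * t), dt=dt)
        assert np.allclose(g, np.sinh(lam * dt) / dt, rtol=1e-12)

    def test_rejects_nonpositive_and_short_series(self):
        with pytest.raises(ValueError, match="positive"):
            relative_rate(np.array([1.0, -1.0, 1.0]))
        with pytest.raises(ValueError, match="length"):
            relative_rate(np.array([1.0, 2.0]))


class TestCrossCorrelation:
    def test_antiphase_signal_minimum_at_zero_lag(self):
        rng = np.random.default_rng(0)
        g1 = rng.standard_normal(300)
        res = cross_correlation(g1, -g1, max_lag=10)
        tau, c = min_lag(res)
        assert tau == 0.0
        assert c == pytest.approx(-np.mean(g1**2), rel=1e-12)

    def test_delayed_sinusoid_recovers_delay_and_amplitude(self):
        dt, tau0, amp = 1.0, 7.0, 1.3
        t = np.arange(2000) * dt
        om = 2 * np.pi / 50.0
        g1 = amp * np.sin(om * t)
        g2 = -amp * np.sin(om * (t - tau0))
        res = cross_correlation(g1, g2, max_lag=25, dt=dt)
        tau, c = min_lag(res)
        assert abs(tau - tau0) <= dt
        assert c == pytest.approx(-0.5 * amp**2, rel=0.05)

    def test_white_noise_stays_within_null_bound(self):
        rng = np.random.default_rng(12)
        n = 500
        g1, g2 = rng.standard_normal(n), rng.standard_normal(n)
        res = cross_correlation(g1, g2, max_lag=20)
        assert np.nanmax(np.abs(res.C)) < 3.0 / np.sqrt(n)

    def test_swap_reflects_about_zero_lag(self):
        rng = np.random.default_rng(3)
        g1, g2 = rng.standard_normal(200), rng.standard_normal(200)
        r12 = cross_correlation(g1, g2, max_lag=8)
        r21 = cross_correlation(g2, g1, max_lag=8)
        assert np.allclose(r12.C, r21.C[::-1], equal_nan=True)

    def test_scale_invariance_of_relative_rates(self):
        """Rescaling the intensity by any positive constant (arbitrary
        fluorescence units) leaves the correlation unchanged."""
        series = gen_coupled_timeseries(n_cells=3, seed=1)
        dt = series[0].dt
        g1a = [relative_rate(s.a_l, dt) for s in series]
        g1b = [relative_rate(17.3 * s.a_l, dt) for s in series]
        g2 = [relative_rate(s.h, dt) for s in series]
        ra = cross_correlation(g1a, g2, max_lag=60, dt=dt)
        rb = cross_correlation(g1b, g2, max_lag=60, dt=dt)
        assert np.allclose(ra.C, rb.C, equal_nan=True)

    def test_sparse_overlap_reported_missing(self):
        g = np.arange(8.0) + 1.0
        res = cross_correlation(g, g, max_lag=5, min_overlap=5)
        assert np.isnan(res.C[0]) and np.isnan(res.C[-1])  # |k|=5 -> 3 samples
        assert not np.isnan(res.C[len(res.C) // 2])


class TestMinLag:
    def test_grid_argmin(self):
        from epifold.fluctuation import CrossCorrResult

        res = CrossCorrResult(
            lags=np.array([-10.0, 0.0, 10.0]),
            C=np.array([0.1, -0.5, 0.2]),
            C_per_cell=np.zeros((1, 3)),
            n_cells=1,
        )
        assert min_lag(res) == (0.0, -0.5)

    def test_tie_broken_toward_smallest_lag(self):
        from epifold.fluctuation import CrossCorrResult

        res = CrossCorrResult(
            lags=np.array([-10.0, 0.0, 10.0, 20.0]),
            C=np.array([-0.5, 0.0, 0.1, -0.5]),
            C_per_cell=np.zeros((1, 4)),
            n_cells=1,
        )
        assert min_lag(res)[0] == -10.0

    def test_generator_delay_recovery(self):
        """12 cells sampled every 10 s with a 22 s coupling delay: the
        cross-correlation minimum falls within one sampling interval of the
        true delay, is negative, and C is negative at nearby positive lags."""
        series = gen_coupled_timeseries(
            n_cells=12, duration=600, dt_sample=10.0, delay=22.0, coupling=1.0, seed=42
        )
        g1, g2, res = pipeline(series)
        tau, c = min_lag(res)
        assert abs(tau - 22.0) <= 10.0
        assert c < 0
        near = (res.lags > 0) & (np.abs(res.lags - tau) <= 10.0)
        assert np.all(res.C[near] < 0)

    def test_zero_coupling_within_null_bound(self):
        series = gen_coupled_timeseries(
            n_cells=12, duration=600, dt_sample=10.0, delay=22.0, coupling=0.0, seed=43
        )
        g1, g2, res = pipeline(series)
        bound = null_bound(g1, g2, max_lag=100.0, dt=10.0)
        assert np.nanmax(np.abs(res.C)) < bound

    def test_weak_fluctuation_regime_decorrelates(self):
        """Cells with weak fluctuations and weak coupling (the neighboring /
        second-fold regime) show a much shallower correlation minimum than
        the strongly fluctuating fold cells at matched n."""
        fold = gen_coupled_timeseries(n_cells=12, seed=7)
        weak = gen_coupled_timeseries(
            n_cells=12, seed=7, fluct_sd=0.04, coupling=0.15, group="neighbor"
        )
        _, _, r_fold = pipeline(fold)
        _, _, r_weak = pipeline(weak)
        assert abs(min_lag(r_weak)[1]) < 0.2 * abs(min_lag(r_fold)[1])
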