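"""Growth-parameter extraction: windowed fits, sanity checks, replicates."""

import math

import numpy as np
import pytest
from scipy.stats import linregress

import plategrowth as pg
from plategrowth.growth import (
    AT_CUTOFF,
    NO_PLATEAU,
    ExtractionConfig,
    _admissible_windows,
    extract_growth_parameters,
    extract_yield,
    windowed_exponential_fit,
)


def grid_search_fit(series, start, omega, mu_range, od0_range, n=121, refine=4):
    """Independent brute-force minimiser of the OD-space objective."""
    t = series.times[start : start + omega + 1]
    y = series.values[start : start + omega + 1]
    lo_mu, hi_mu = mu_range
    lo_a, hi_a = od0_range
    best = None
    for _ in range(refine):
        mus = np.linspace(lo_mu, hi_mu, n)
        ods = np.linspace(lo_a, hi_a, n)
        sse = (
            (ods[:, None, None] * np.exp(mus[None, :, None] * t[None, None, :]) - y)
            ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (mus[j], ods[i])
        dmu = (hi_mu - lo_mu) / (n - 1)
        da = (hi_a - lo_a) / (n - 1)
        lo_mu, hi_mu = mus[j] - 2 * dmu, mus[j] + 2 * dmu
        lo_a, hi_a = max(ods[i] - 2 * da, 1e-12), ods[i] + 2 * da
    return best


class TestWindowedFit:
    def test_exact_exponential_recovered(self, exp_series):
        mu, od0, rms = windowed_exponential_fit(exp_series, 5, 10)
        assert mu == pytest.approx(0.4, abs=1e-9)
        assert od0 == pytest.approx(0.02, abs=1e-9)
        assert rms < 1e-12

    def test_constant_series_gives_zero_rate(self):
        t = np.arange(0, 5, 0.25)
        series = pg.TimeSeries(t, np.full(t.size, 0.3))
        mu, od0, _ = windowed_exponential_fit(series, 0, 10)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert od0 == pytest.approx(0.3, abs=1e-12)

    def test_nonpositive_window_rejected(self):
        t = np.arange(0, 5, 0.25)
        v = np.full(t.size, 0.3)
        v[4] = -0.01
        series = pg.TimeSeries(t, v)
        with pytest.raises(ValueError, match="non-positive"):
            windowed_exponential_fit(series, 0, 10)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 6, 0.25)
        for _ in range(6):
            mu_true = rng.uniform(0.2, 0.7)
            od0_true = rng.uniform(0.01, 0.05)
            y = od0_true * np.exp(mu_true * t) * (1 + rng.normal(0, 0.02, t.size))
            series = pg.TimeSeries(t, np.abs(y))
            start = int(rng.integers(0, t.size - 11))
            mu, od0, _ = windowed_exponential_fit(series, start, 10)
            mu_g, _ = grid_search_fit(
                series, start, 10, (0.0, 1.2), (od0_true * 0.3, od0_true * 3)
            )
            assert mu == pytest.approx(mu_g, abs=1e-3)


class TestExtractGrowthParameters:
    def test_noiseless_logistic_recovery(self, logistic_series):
        series, truth = logistic_series
        p = extract_growth_parameters(series)
        assert p.valid
        assert p.mu_max == pytest.approx(truth["r"], rel=0.05)
        assert p.lag_time == pytest.approx(truth["lag_true"], abs=0.25)
        assert p.doubling_time == pytest.approx(math.log(2) / p.mu_max, rel=1e-12)
        assert p.yield_biomass == pytest.approx(truth["k"], rel=0.02)

    def test_pure_exponential_at_baseline_has_zero_lag(self):
        t = np.arange(0, 12, 0.25)
        series = pg.TimeSeries(t, 0.05 * np.exp(0.5 * t))
        config = ExtractionConfig(
            lag_baseline_od=0.05, smoothing_half_width=0, allow_at_cutoff=True
        )
        p = extract_growth_parameters(series, config)
        assert p.lag_time == pytest.approx(0.0, abs=1e-6)

    def test_at_cutoff_invalidates_unless_allowed(self, logistic_series):
        # a logistic's rate declines after the lag, so an interval placed
        # inside the exponential phase pins the maximum at its lower edge
        series, _ = logistic_series
        config = ExtractionConfig(
            mu_time_interval=(4.0, 8.0), smoothing_half_width=0
        )
        p = extract_growth_parameters(series, config)
        assert not p.valid
        assert AT_CUTOFF in p.warnings
        relaxed = extract_growth_parameters(
            series,
            ExtractionConfig(
                mu_time_interval=(4.0, 8.0),
                smoothing_half_width=0,
                allow_at_cutoff=True,
            ),
        )
        assert relaxed.valid
        assert AT_CUTOFF in relaxed.warnings

    def test_too_short_series_invalid(self):
        series = pg.TimeSeries(np.arange(5.0), np.full(5, 0.5))
        p = extract_growth_parameters(series, ExtractionConfig(window_omega=10))
        assert not p.valid

    def test_all_windows_below_threshold_flagged(self):
        t = np.arange(0, 10, 0.25)
        series = pg.TimeSeries(t, np.full(t.size, 0.001))
        p = extract_growth_parameters(series)
        assert not p.valid
        assert "BELOW_OD_THRESHOLD" in p.warnings

    def test_mu_max_equals_exhaustive_brute_force(self, logistic_series):
        # same admissibility rules, re-enumerated independently
        series, _ = logistic_series
        config = ExtractionConfig()
        from plategrowth.preprocess import smooth_series

        smoothed = smooth_series(series, config.smoothing_half_width)
        p = extract_growth_parameters(series, config)
        admissible, _ = _admissible_windows(smoothed, config)
        mus = []
        for s in admissible:
            mu, _, _ = windowed_exponential_fit(smoothed, s, config.window_omega)
            mus.append(mu)
        assert p.mu_max == max(mus)  # bit-for-bit

    def test_time_scaling_property(self, noiseless_sim):
        series, _ = pg.simulate_growth_curve(pg.WellSpec(), noiseless_sim)
        k = 2.0
        scaled = pg.TimeSeries(series.times * k, series.values)
        config = ExtractionConfig(lag_baseline_od=0.05)
        config_scaled = ExtractionConfig(
            lag_baseline_od=0.05, yield_window=config.yield_window * k
        )
        p = extract_growth_parameters(series, config)
        q = extract_growth_parameters(scaled, config_scaled)
        assert q.mu_max == pytest.approx(p.mu_max / k, rel=1e-6)
        assert q.lag_time == pytest.approx(p.lag_time * k, rel=1e-6)


class TestYield:
    def test_saturating_logistic_yield(self, noiseless_sim):
        series, truth = pg.simulate_growth_curve(pg.WellSpec(), noiseless_sim)
        y, warnings = extract_yield(series)
        assert not warnings
        assert y == pytest.approx(truth["k"], rel=0.02)

    def test_steep_line_has_no_plateau(self):
        t = np.arange(0, 10, 0.25)
        series = pg.TimeSeries(t, 0.1 + 0.2 * t)
        y, warnings = extract_yield(series)
        assert NO_PLATEAU in warnings
        assert math.isnan(y)

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(5)
        sim = pg.SimSpec(cycle_minutes=15)
        series, _ = pg.simulate_growth_curve(pg.WellSpec(), sim, seed=rng)
        config = ExtractionConfig()
        y, _ = extract_yield(series, config)
        # oracle: regress every window of the configured duration directly
        t, v = series.times, series.values
        best = -math.inf
        for s in range(len(t)):
            e = int(np.searchsorted(t, t[s] + config.yield_window, side="right"))
            if e - s < 2 or t[e - 1] - t[s] < config.yield_window * 0.5:
                continue
            if abs(linregress(t[s:e], v[s:e]).slope) <= config.yield_slope_tol:
                best = max(best, v[s:e].max())
        assert y == best


class TestReplicates:
    def _experiment(self, n=3):
        t = np.arange(0, 2, 0.5)
        wells = [
            pg.WellRecord(f"A{i}", "FY4", "YPD", pg.TimeSeries(t, np.full(t.size, 0.1)))
            for i in range(1, n + 1)
        ]
        return pg.PlateExperiment(wells=wells)

    def _params(self, mu):
        return pg.GrowthParameters(
            mu_max=mu, t_at_mu_max=3.0, od0_fit=0.01,
            lag_time=1.0, doubling_time=math.log(2) / mu,
            yield_biomass=1.2, valid=True,
        )

    def test_mean_and_unbiased_variance(self):
        exp = self._experiment()
        results = {f"A{i}": self._params(m) for i, m in zip((1, 2, 3), (0.48, 0.50, 0.52))}
        summaries = pg.aggregate_replicates(results, exp, parameters=("mu_max",))
        (s,) = summaries
        assert s.n == 3
        assert s.mean == pytest.approx(0.50)
        assert s.variance == pytest.approx(0.0004)

    def test_blacklisted_well_excluded(self):
        exp = self._experiment()
        exp.well("A2").blacklisted = True
        results = {f"A{i}": self._params(0.5) for i in (1, 2, 3)}
        (s,) = pg.aggregate_replicates(results, exp, parameters=("mu_max",))
        assert s.n == 2
        assert s.n_excluded == 1

    def test_all_invalid_gives_empty_summary(self):
        exp = self._experiment()
        results = {f"A{i}": pg.GrowthParameters(valid=False) for i in (1, 2, 3)}
        (s,) = pg.aggregate_replicates(results, exp, parameters=("mu_max",))
        assert s.n == 0
        assert math.isnan(s.mean)

    def test_single_well_variance_zero(self):
        exp = self._experiment(n=1)
        (s,) = pg.aggregate_replicates(
            {"A1": self._params(0.5)}, exp, parameters=("mu_max",)
        )
        assert s.n == 1
        assert s.variance == 0.0


class TestFitnessRatio:
    def _summary(self, condition, mean, n=3):
        return pg.ReplicateSummary(
            sample="FY4", condition=condition, parameter="mu_max",
            n=n, mean=mean, variance=0.0,
        )

    def test_ratio_to_reference(self):
        rows = pg.fitness_ratio(
            [self._summary("YNB", 0.50), self._summary("NaCl", 0.25)], "YNB"
        )
        by_cond = {r["condition"]: r["ratio"] for r in rows}
        assert by_cond["NaCl"] == pytest.approx(0.5)
        assert by_cond["YNB"] == pytest.approx(1.0)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="FY4"):
            pg.fitness_ratio([self._summary("NaCl", 0.25)], "YNB")

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            pg.fitness_ratio(
                [self._summary("YNB", math.nan, n=0), self._summary("NaCl", 0.25)],
                "YNB",
            )
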