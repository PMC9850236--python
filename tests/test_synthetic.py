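"""Synthetic-data generator: calibration, determinism, and the
generative/estimand consistency oracle."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from coldpm.basis import CrossBasisSpec, build_crossbasis, moving_average
from coldpm.errors import CalibrationError, ConfigError, DataError
from coldpm.synthetic import (PMParams, RHParams, SimulationConfig, TempParams,
                              TrueSurfaceSpec, calibrate_surface,
                              simulate_deaths, simulate_pm, simulate_study,
                              simulate_weather)


def _flat_temp(c, sd=0.0, ar=0.0, **kw):
    return TempParams(plateau=c, base=c, end_level=c, sd_winter=sd,
                      sd_autumn=sd, ar=ar, **kw)


class TestWeather:
    def test_zero_noise_gives_constant_series_at_mean(self):
        cfg = SimulationConfig(seed=1, temp_params=_flat_temp(2.5),
                               rh_params=RHParams(mean=60, sd=0))
        w = simulate_weather(cfg)
        assert np.allclose(w["temp_c"], 2.5)
        assert np.allclose(w["rh_pct"], 60.0)

    def test_same_seed_reproduces_identical_series(self):
        a = simulate_weather(SimulationConfig(seed=7))
        b = simulate_weather(SimulationConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_weather(SimulationConfig(seed=8))
        assert not np.allclose(a["temp_c"], c["temp_c"])

    def test_dates_cover_only_season_plus_leadin(self):
        cfg = SimulationConfig(seed=1, n_seasons=2)
        w = simulate_weather(cfg)
        months = pd.DatetimeIndex(w["date"]).month
        assert set(months) <= {10, 11, 12, 1, 2}

    def test_median_calibrated_to_observed_cold_season(self):
        """At ~10,000 days the sample median matches the observed
        registry median (1.17 degC) within half a degree."""
        cfg = SimulationConfig(seed=11, n_seasons=74)
        w = simulate_weather(cfg)
        t = w.loc[cfg.is_analysis_day(w["date"]), "temp_c"]
        assert len(t) > 8000
        assert abs(np.median(t) - 1.17) < 0.5

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(temp_params=TempParams(sd_winter=-1.0))
        with pytest.raises(ConfigError):
            SimulationConfig(temp_params=TempParams(ar=1.5))


class TestPM:
    def test_degenerate_noise_gives_constant_at_median(self):
        cfg = SimulationConfig(
            seed=2, temp_params=_flat_temp(0.0),
            pm_params={"pm1": PMParams(np.log(50), 0.0, coupling=0.0),
                       "pm25": PMParams(np.log(80), 0.0, coupling=0.0)})
        w = simulate_weather(cfg).set_index("date")
        pm = simulate_pm(cfg, w["temp_c"])
        assert np.allclose(pm["pm1"], 50.0)
        assert np.allclose(pm["pm25"], 80.0)

    def test_medians_calibrated_to_observed_registry_values(self):
        cfg = SimulationConfig(seed=3, n_seasons=74)
        w = simulate_weather(cfg).set_index("date")
        pm = simulate_pm(cfg, w["temp_c"])
        mask = cfg.is_analysis_day(pm.index)
        assert np.median(pm.loc[mask, "pm25"]) == pytest.approx(81.34, rel=0.05)
        assert np.median(pm.loc[mask, "pm1"]) == pytest.approx(51.78, rel=0.05)

    def test_negative_coupling_gives_negative_temp_correlation(self):
        cfg = SimulationConfig(seed=4, n_seasons=30)
        w = simulate_weather(cfg).set_index("date")
        pm = simulate_pm(cfg, w["temp_c"])
        anom = w["temp_c"] - cfg.temp_params.seasonal_mean(w.index)
        r = np.corrcoef(anom, np.log(pm["pm1"]))[0, 1]
        assert r < 0

    def test_pollutant_noise_correlation(self):
        cfg = SimulationConfig(seed=5, n_seasons=30)
        w = simulate_weather(cfg).set_index("date")
        pm = simulate_pm(cfg, w["temp_c"])
        r = np.corrcoef(np.log(pm["pm1"]), np.log(pm["pm25"]))[0, 1]
        assert r > 0.5


class TestCalibration:
    def _spec_p1(self, seed=6):
        cfg = SimulationConfig(seed=seed)
        w = simulate_weather(cfg)
        t = w.loc[cfg.is_analysis_day(w["date"]), "temp_c"].to_numpy()
        return CrossBasisSpec.from_data(t), float(np.percentile(t, 1))

    def test_target_or_round_trip_to_1e8(self, overall_study):
        t = overall_study.truth
        from coldpm.effects import cumulative_contrast
        a = cumulative_contrast(t.spec, t.p1_temp, t.true_mmt)
        assert np.exp(a @ t.beta_star) == pytest.approx(1.83, abs=1e-8)
        assert len(t.beta_star) == len(t.gamma_star) == t.spec.n_columns

    def test_unit_or_gives_zero_cumulative_contrast(self):
        spec, p1 = self._spec_p1()
        truth = calibrate_surface(1.0, 0.0, 18.5, spec, p1)
        assert truth.base_log_or == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(truth.beta_star, 0.0)

    def test_zero_pct_gives_zero_gamma(self):
        spec, p1 = self._spec_p1()
        truth = calibrate_surface(1.83, 0.0, 18.5, spec, p1)
        assert np.allclose(truth.gamma_star, 0.0)

    def test_true_mmt_is_argmin_of_implied_curve(self, overall_study):
        from coldpm.basis import cumulative_lag_weights, ns_basis
        t = overall_study.truth
        w = t.beta_star.reshape(t.spec.var_spec.df, t.spec.lag_spec.df)
        wv = w @ cumulative_lag_weights(t.spec)
        b0, b1 = t.spec.var_spec.boundary_knots
        grid = np.arange(b0, b1, 0.05)
        f = ns_basis(grid, t.spec.var_spec) @ wv
        assert abs(grid[np.argmin(f)] - t.true_mmt) < 0.21

    def test_unattainable_mmt_raises(self):
        spec, p1 = self._spec_p1()
        with pytest.raises(CalibrationError):
            calibrate_surface(1.83, 0.0, 50.0, spec, p1)

    def test_pct_inversion(self):
        spec, p1 = self._spec_p1()
        truth = calibrate_surface(1.83, 7.6, 18.5, spec, p1, anchor_pm=55.0)
        assert truth.pct_per_10 == pytest.approx(7.6, abs=1e-10)
        assert truth.true_or(55.0) == pytest.approx(1.83, abs=1e-10)


class TestDeaths:
    def test_null_surface_mean_count_matches_baseline(self):
        cfg = SimulationConfig(
            seed=9, n_seasons=2, baseline_rate=300.0,
            truth=TrueSurfaceSpec(target_or_p1=1.0, pct_per_10=0.0, theta_pm=0.0))
        s = simulate_study(cfg)
        daily = s.deaths.groupby("date")["n_deaths"].sum()
        assert daily.mean() == pytest.approx(300.0, rel=0.02)

    def test_seed_reproducibility_of_records(self):
        cfg = SimulationConfig(seed=10, n_seasons=2, baseline_rate=50.0)
        a = simulate_study(cfg).deaths
        b = simulate_study(cfg).deaths
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_leadin_raises_with_first_valid_date(self):
        s = simulate_study(SimulationConfig(seed=11, n_seasons=1, baseline_rate=30.0))
        exp = s.exposures.copy()
        exp = exp.iloc[10:]  # destroy part of the lead-in
        cfg = SimulationConfig(seed=11, n_seasons=1, baseline_rate=30.0)
        with pytest.raises(DataError, match="lead-in"):
            simulate_deaths(cfg, exp, s.truth)

    def test_expanded_records_match_aggregated_totals(self):
        cfg = SimulationConfig(seed=12, n_seasons=1, baseline_rate=20.0)
        s = simulate_study(cfg)
        expanded = simulate_study(cfg, expanded=True).deaths
        assert len(expanded) == s.deaths["n_deaths"].sum()
        assert (expanded["n_deaths"] == 1).all()

    def test_subgroup_proportions_match_configuration(self):
        cfg = SimulationConfig(seed=13, n_seasons=2, baseline_rate=500.0)
        s = simulate_study(cfg)
        share = s.deaths.groupby("sex")["n_deaths"].sum()
        share = share / share.sum()
        assert share["male"] == pytest.approx(0.5597, abs=0.01)

    def test_misspecified_mode_produces_out_of_family_truth(self):
        # quadratic truth outside the spline family still simulates
        cfg = SimulationConfig(seed=17, n_seasons=1, baseline_rate=50.0,
                               misspecified=True)
        s = simulate_study(cfg)
        assert s.deaths["n_deaths"].sum() > 0

    def test_empirical_rate_ratio_matches_target_or(self):
        """Large-count oracle: day-blocks whose whole lag history sits
        at the P1 temperature versus at the MMT must show an empirical
        death-rate ratio equal to the calibrated cumulative OR."""
        base = SimulationConfig(seed=14)
        w = simulate_weather(base)
        t_a = w.loc[base.is_analysis_day(w["date"]), "temp_c"].to_numpy()
        spec = CrossBasisSpec.from_data(t_a)
        p1 = float(np.percentile(t_a, 1))
        truth = calibrate_surface(1.83, 0.0, 18.5, spec, p1, theta_pm=0.0)

        # hand-built exposures: Nov-Dec pinned at the MMT, Jan-Feb at P1
        cfg = replace(base, n_seasons=1, baseline_rate=12000.0,
                      temp_params=_flat_temp(0.0),
                      pm_params={"pm1": PMParams(np.log(50), 0.0, coupling=0.0),
                                 "pm25": PMParams(np.log(80), 0.0, coupling=0.0)})
        dates = cfg.all_dates()
        temp = np.where(dates < pd.Timestamp("2014-01-01"), truth.true_mmt, p1)
        exp = pd.DataFrame({"date": dates, "temp_c": temp, "rh_pct": 60.0,
                            "pm1": 50.0, "pm25": 80.0, "ozone": 50.0})
        deaths = simulate_deaths(cfg, exp, truth)
        daily = deaths.groupby("date")["n_deaths"].sum()
        # discard transition days whose lag window mixes both levels
        at_mmt = daily.loc["2013-11-14":"2013-12-31"]
        at_p1 = daily.loc["2014-01-13":"2014-02-28"]
        ratio = at_p1.mean() / at_mmt.mean()
        assert ratio == pytest.approx(1.83, rel=0.01)
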