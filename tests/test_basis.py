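"""Spline bases, moving averages, and the crossbasis construction."""

import numpy as np
import pandas as pd
import pytest

from coldpm.basis import (CrossBasisSpec, SplineSpec, build_crossbasis,
                          lag_basis_knots, lag_basis_values, moving_average,
                          ns_basis)
from coldpm.errors import ConfigError, DataError


def truncated_power_natural_basis(x, knots):
    """Independent oracle: ESL-style truncated-power natural cubic
    spline basis (includes the constant) for the given full knot
    sequence (boundary knots included)."""
    x = np.asarray(x, float)
    xi = np.asarray(knots, float)
    K = len(xi)

    def d(k):
        return (np.clip(x - xi[k], 0, None) ** 3
                - np.clip(x - xi[K - 1], 0, None) ** 3) / (xi[K - 1] - xi[k])

    cols = [np.ones_like(x), x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def _projection_residual(A, B):
    """Max residual norm of columns of B projected onto colspace(A)."""
    Q, _ = np.linalg.qr(A)
    resid = B - Q @ (Q.T @ B)
    return np.abs(resid).max()


class TestNsBasis:
    def test_spans_truncated_power_space(self):
        spec = SplineSpec(df=3, internal_knots=(-1.0, 3.0), boundary_knots=(-10.0, 20.0))
        x = np.linspace(-14, 25, 301)  # includes points beyond both boundaries
        ours = np.column_stack([np.ones_like(x), ns_basis(x, spec)])
        oracle = truncated_power_natural_basis(x, [-10.0, -1.0, 3.0, 20.0])
        assert _projection_residual(ours, oracle) < 1e-8
        assert _projection_residual(oracle, ours) < 1e-8

    def test_second_derivative_zero_outside_boundaries(self):
        spec = SplineSpec(df=4, internal_knots=(1.0, 2.0, 5.0), boundary_knots=(0.0, 8.0))
        for x0 in (-3.0, 9.5):
            h = 0.25
            vals = ns_basis(np.array([x0 - h, x0, x0 + h]), spec)
            second_diff = vals[0] - 2 * vals[1] + vals[2]
            assert np.abs(second_diff).max() < 1e-10

    def test_equal_inputs_give_identical_rows(self):
        spec = SplineSpec(df=3, internal_knots=(0.5, 1.5), boundary_knots=(0.0, 2.0))
        out = ns_basis(np.full(5, 1.2), spec)
        assert np.allclose(out, out[0])

    def test_quantile_rule_df3_gives_two_internal_knots(self):
        # knots resolved from the observed cold-season quantiles
        rng = np.random.default_rng(0)
        temps = rng.normal(1.17, 4.3, 2000)
        spec = SplineSpec.from_quantiles(temps, df=3)
        assert len(spec.internal_knots) == 2
        assert spec.boundary_knots == (temps.min(), temps.max())

    @pytest.mark.parametrize("df,knots,bounds", [
        (0, (), (0, 1)),
        (3, (2.0, 1.0), (0.0, 3.0)),     # unordered
        (3, (0.5, 1.5), (2.0, 1.0)),     # reversed boundaries
    ])
    def test_invalid_specs_rejected(self, df, knots, bounds):
        with pytest.raises(ConfigError):
            SplineSpec(df=df, internal_knots=knots, boundary_knots=bounds)


class TestMovingAverage:
    def _series(self, values, start="2015-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        return pd.Series(values, index=idx)

    def test_constant_series(self):
        out = moving_average(self._series([3.5] * 30), (0, 12))
        assert np.allclose(out.iloc[12:], 3.5)
        assert out.iloc[:12].isna().all()

    def test_arithmetic_mean_of_ramp(self):
        out = moving_average(self._series(np.arange(13.0)), (0, 12))
        assert out.iloc[12] == pytest.approx(6.0)

    def test_missing_day_propagates(self):
        vals = np.arange(30.0)
        s = self._series(vals)
        s.iloc[15] = np.nan
        out = moving_average(s, (0, 2))
        assert out.iloc[15:18].isna().all()
        assert not out.iloc[18:].isna().any()

    def test_calendar_gap_counts_as_missing(self):
        s = self._series(np.arange(10.0))
        s = s.drop(s.index[4])
        out = moving_average(s, (0, 2))
        # windows touching the dropped calendar day are missing
        assert np.isnan(out.loc["2015-01-06"])
        assert out.loc["2015-01-09"] == pytest.approx(7.0)

    def test_window_longer_than_series_warns_all_missing(self):
        with pytest.warns(UserWarning):
            out = moving_average(self._series([1.0, 2.0]), (0, 12))
        assert out.isna().all()


class TestLagKnots:
    def test_count_order_and_range(self):
        knots = lag_basis_knots((0, 12), df=4)
        assert len(knots) == 2
        assert all(0 < k < 12 for k in knots)
        assert np.all(np.diff(knots) > 0)

    def test_log_rule_denser_at_short_lags(self):
        knots = np.array(lag_basis_knots((0, 12), df=5))
        gaps = np.diff(np.r_[0.0, knots, 12.0])
        assert np.all(np.diff(gaps) > 0)

    def test_df3_knot_at_log_median(self):
        (knot,) = lag_basis_knots((0, 12), df=3)
        assert knot == pytest.approx(np.sqrt(13.0) - 1.0, abs=1e-12)

    def test_lag_basis_nonzero_at_lag_zero(self):
        # the intercept-bearing lag basis can represent effects on the
        # first day of exposure
        spec = SplineSpec(4, lag_basis_knots((0, 12), 4), (0.0, 12.0),
                          intercept=True)
        row0 = ns_basis(np.array([0.0]), spec)
        assert np.abs(row0).max() > 0.1


def crossbasis_bruteforce(temps, spec):
    """Direct double-loop summation oracle for the crossbasis rows."""
    l0, l1 = spec.lag_range
    lags = np.arange(l0, l1 + 1)
    C = ns_basis(lags.astype(float), spec.lag_spec)
    n = len(temps)
    out = np.full((n, spec.n_columns), np.nan)
    for t in range(n):
        if t - l1 < 0:
            continue
        row = np.zeros((spec.var_spec.df, spec.lag_spec.df))
        for i, lag in enumerate(lags):
            r = ns_basis(float(temps[t - lag]), spec.var_spec)
            for j in range(spec.var_spec.df):
                for k in range(spec.lag_spec.df):
                    row[j, k] += r[j] * C[i, k]
        out[t] = row.ravel()
    return out


class TestCrossBasis:
    def _temp_series(self, n=40, seed=5):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2015-01-01", periods=n, freq="D")
        return pd.Series(rng.normal(2.0, 5.0, n), index=idx)

    def test_matches_bruteforce_double_loop(self):
        temp = self._temp_series()
        spec = CrossBasisSpec.from_data(temp.to_numpy())
        cb = build_crossbasis(temp, spec)
        oracle = crossbasis_bruteforce(temp.to_numpy(), spec)
        got = cb.values.to_numpy()
        valid = ~np.isnan(oracle).any(axis=1)
        assert valid.sum() == len(temp) - 12
        assert np.abs(got[valid] - oracle[valid]).max() < 1e-12
        assert np.isnan(got[~valid]).all()

    def test_default_spec_has_12_columns(self):
        temp = self._temp_series()
        spec = CrossBasisSpec.from_data(temp.to_numpy())
        assert spec.n_columns == 12
        assert build_crossbasis(temp, spec).values.shape[1] == 12

    def test_constant_series_gives_identical_valid_rows(self):
        idx = pd.date_range("2015-01-01", periods=30, freq="D")
        temp = pd.Series(4.0, index=idx)
        spec = CrossBasisSpec(
            var_spec=SplineSpec(3, (2.0, 6.0), (0.0, 10.0)),
            lag_spec=SplineSpec(4, lag_basis_knots((0, 12), 4), (0.0, 12.0),
                            intercept=True))
        vals = build_crossbasis(temp, spec).values.dropna()
        assert np.allclose(vals.to_numpy(), vals.iloc[0].to_numpy())

    def test_valid_from_respects_lag_leadin(self):
        temp = self._temp_series()
        spec = CrossBasisSpec.from_data(temp.to_numpy())
        cb = build_crossbasis(temp, spec)
        assert cb.valid_from == temp.index[12]

    def test_all_missing_raises(self):
        idx = pd.date_range("2015-01-01", periods=5, freq="D")
        temp = pd.Series(1.0, index=idx)
        spec = CrossBasisSpec(
            var_spec=SplineSpec(3, (0.5, 1.5), (0.0, 2.0)),
            lag_spec=SplineSpec(4, lag_basis_knots((0, 12), 4), (0.0, 12.0),
                            intercept=True))
        with pytest.raises(DataError):
            build_crossbasis(temp, spec)
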