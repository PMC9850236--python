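"""Natural cubic spline bases, lagged moving averages, and the
temperature exposure-lag crossbasis.

The crossbasis is the tensor-product design of a distributed lag
non-linear model (DLNM): one natural cubic spline basis over the
exposure (temperature) dimension and one over the lag dimension, with
row ``t``, column ``(j, k)`` equal to

    sum_{l = L0..L1}  R_j(temp[t - l]) * C_k(l)

where ``R`` is the variable-dimension basis and ``C`` the lag-dimension
basis evaluated on integer lags.  The temperature basis carries no
intercept (stratum constants absorb exposure-independent levels in the
conditional-logistic likelihood downstream); the lag basis does carry
one, since a lag-constant response to temperature is a real,
identifiable shape — without it every fitted surface would be pinned to
zero at lag 0.

Natural splines are built from a cubic B-spline design with the natural
(zero second derivative at the boundary knots) constraint applied by
post-multiplication, and extended linearly beyond the boundary knots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import ConfigError, DataError

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "ns_basis",
    "moving_average",
    "lag_basis_knots",
    "build_crossbasis",
    "lag_basis_values",
    "cumulative_lag_weights",
]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of one natural cubic spline basis.

    Parameters
    ----------
    df : int
        Number of basis columns.  Without an intercept a natural cubic
        spline with ``df`` columns has ``df - 1`` internal knots; with an
        intercept it has ``df - 2``.
    internal_knots : tuple of float
        Strictly increasing knots strictly inside the boundary knots.
    boundary_knots : (float, float)
        Natural-constraint boundaries; the basis is linear beyond them.
    intercept : bool
        Whether the basis spans constants.  Default False.
    """

    df: int
    internal_knots: tuple
    boundary_knots: tuple
    intercept: bool = False

    def __post_init__(self):
        if self.df < 1:
            raise ConfigError(f"spline df must be >= 1, got {self.df}")
        b0, b1 = self.boundary_knots
        if not b0 < b1:
            raise ConfigError(f"boundary knots must be increasing, got {self.boundary_knots}")
        ik = np.asarray(self.internal_knots, dtype=float)
        if ik.size and (np.any(np.diff(ik) <= 0) or ik.min() <= b0 or ik.max() >= b1):
            raise ConfigError(
                "internal knots must be strictly increasing and strictly "
                f"inside the boundary knots; got {self.internal_knots} in {self.boundary_knots}"
            )
        expected = len(ik) + (2 if self.intercept else 1)
        if self.df != expected:
            raise ConfigError(
                f"df={self.df} inconsistent with {len(ik)} internal knots "
                f"(intercept={self.intercept}; expected df={expected})"
            )

    @classmethod
    def from_quantiles(cls, x, df, intercept=False):
        """Default knot rule: internal knots at equally spaced quantiles
        of the observed values, boundary knots at the observed min/max."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise DataError("need at least two finite observations to place knots")
        n_internal = df - (2 if intercept else 1)
        if n_internal < 0:
            raise ConfigError(f"df={df} too small for intercept={intercept}")
        probs = np.arange(1, n_internal + 1) / (n_internal + 1)
        knots = np.quantile(x, probs, method="linear") if n_internal else np.array([])
        return cls(df=df, internal_knots=tuple(knots),
                   boundary_knots=(float(x.min()), float(x.max())),
                   intercept=intercept)


def _bspline_design(x, aknots, nu=0):
    """Cubic B-spline design matrix (or its nu-th derivative) at x.

    ``aknots`` is the augmented knot vector with 4-fold boundary knots.
    x must lie within the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    n_basis = len(aknots) - 4
    out = np.empty((x.size, n_basis))
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        spl = BSpline(aknots, c, 3, extrapolate=True)
        if nu:
            spl = spl.derivative(nu)
        out[:, i] = spl(x)
    return out


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an ``(n, spec.df)`` matrix.  Beyond the boundary knots the
    basis continues linearly (first-order Taylor expansion about the
    nearest boundary knot), so the second derivative vanishes outside
    the boundaries as the natural constraint requires.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x).astype(float)
    b0, b1 = spec.boundary_knots
    aknots = np.concatenate([[b0] * 4, np.asarray(spec.internal_knots, float), [b1] * 4])

    inner = np.clip(x, b0, b1)
    basis = _bspline_design(inner, aknots)
    lo, hi = x < b0, x > b1
    if np.any(lo):
        d = _bspline_design(np.array([b0]), aknots, nu=1)
        basis[lo] += (x[lo] - b0)[:, None] * d
    if np.any(hi):
        d = _bspline_design(np.array([b1]), aknots, nu=1)
        basis[hi] += (x[hi] - b1)[:, None] * d

    # Natural constraint: zero 2nd derivative at both boundaries.
    const = _bspline_design(np.array([b0, b1]), aknots, nu=2)
    if not spec.intercept:
        basis = basis[:, 1:]
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    out = basis @ q[:, 2:]
    nan_rows = ~np.isfinite(x)
    if np.any(nan_rows):
        out[nan_rows] = np.nan
    return out[0] if scalar else out


def moving_average(x: pd.Series, lag_range=(0, 12)) -> pd.Series:
    """Arithmetic mean of ``x`` over lags ``lag_range[0]..lag_range[1]``.

    The series must be indexed by dates; it is re-indexed to consecutive
    days so calendar gaps count as missing.  A day whose lag window
    touches any missing value is itself missing.
    """
    l0, l1 = int(lag_range[0]), int(lag_range[1])
    if l0 < 0 or l1 <= l0:
        raise ConfigError(f"invalid lag range {lag_range}")
    if not isinstance(x.index, pd.DatetimeIndex):
        raise DataError("moving_average requires a DatetimeIndex")
    full = pd.date_range(x.index.min(), x.index.max(), freq="D")
    s = x.reindex(full)
    window = l1 - l0 + 1
    if window > len(s):
        warnings.warn("lag window longer than series: all output missing")
        return pd.Series(np.nan, index=x.index, name=x.name)
    out = s.rolling(window, min_periods=window).mean().shift(l0)
    return out.reindex(x.index)


def lag_basis_knots(lag_range=(0, 12), df=4, intercept=True):
    """Default internal knots for the lag dimension.

    Knots at equally spaced quantiles of ``log(lag + 1)`` over the
    continuous lag range, i.e. denser at short lags where the response
    changes fastest.  The lag basis carries an intercept (the standard
    DLNM convention: a lag-constant effect is a real, identifiable
    shape), so a natural spline with ``df`` columns has ``df - 2``
    internal knots.
    """
    if df < 2:
        raise ConfigError("lag df must be >= 2")
    n_internal = df - (2 if intercept else 1)
    l0, l1 = lag_range
    lo, hi = np.log(l0 + 1.0), np.log(l1 + 1.0)
    probs = np.arange(1, n_internal + 1) / (n_internal + 1)
    return tuple(np.exp(lo + probs * (hi - lo)) - 1.0)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Crossbasis specification: variable- and lag-dimension splines.

    Defaults follow the analysis model: 3 df for temperature, 4 df for
    lag, lags 0-12 days, giving a 12-column crossbasis.
    """

    var_spec: SplineSpec
    lag_spec: SplineSpec
    lag_range: tuple = (0, 12)

    def __post_init__(self):
        l0, l1 = self.lag_range
        if l0 < 0 or l1 <= l0:
            raise ConfigError(f"invalid lag range {self.lag_range}")

    @classmethod
    def from_data(cls, temps, var_df=3, lag_range=(0, 12), lag_df=4,
                  var_knots=None, var_boundary=None, lag_knots=None):
        """Resolve knots from the observed temperature distribution and
        the log-lag rule.  Explicit knots override the defaults."""
        if var_knots is None or var_boundary is None:
            auto = SplineSpec.from_quantiles(temps, var_df)
            var_knots = auto.internal_knots if var_knots is None else tuple(var_knots)
            var_boundary = auto.boundary_knots if var_boundary is None else tuple(var_boundary)
        var_spec = SplineSpec(var_df, tuple(var_knots), tuple(var_boundary))
        if lag_knots is None:
            lag_knots = lag_basis_knots(lag_range, lag_df)
        lag_spec = SplineSpec(lag_df, tuple(lag_knots),
                              (float(lag_range[0]), float(lag_range[1])),
                              intercept=True)
        return cls(var_spec=var_spec, lag_spec=lag_spec, lag_range=tuple(lag_range))

    @property
    def n_columns(self):
        return self.var_spec.df * self.lag_spec.df

    def column_names(self, prefix="cb"):
        return [f"{prefix}_{j}_{k}" for j in range(self.var_spec.df)
                for k in range(self.lag_spec.df)]


def lag_basis_values(spec: CrossBasisSpec) -> np.ndarray:
    """Lag-dimension basis ``C`` evaluated on the integer lags, shape
    ``(n_lags, lag_df)``."""
    lags = np.arange(spec.lag_range[0], spec.lag_range[1] + 1, dtype=float)
    return ns_basis(lags, spec.lag_spec)


def cumulative_lag_weights(spec: CrossBasisSpec) -> np.ndarray:
    """``c_k = sum_l C_k(l)``: weights that cumulate the lag dimension."""
    return lag_basis_values(spec).sum(axis=0)


@dataclass
class CrossBasisMatrix:
    """Day-by-(vx*vl) crossbasis values for one exposure series.

    ``values`` is indexed by date; rows whose lag history is incomplete
    are NaN.  ``valid_from`` is the first date with complete history.
    """

    values: pd.DataFrame
    spec: CrossBasisSpec
    valid_from: pd.Timestamp = field(default=None)


def build_crossbasis(temp: pd.Series, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Build the exposure-lag crossbasis for a daily temperature series.

    Rows before ``lag_range[1]`` days of history (or touching a missing
    day) are flagged missing rather than dropped, so the caller can drop
    whole case-crossover strata symmetrically.
    """
    if not isinstance(temp.index, pd.DatetimeIndex):
        raise DataError("build_crossbasis requires a DatetimeIndex")
    l0, l1 = spec.lag_range
    full = pd.date_range(temp.index.min(), temp.index.max(), freq="D")
    s = temp.reindex(full).to_numpy(dtype=float)
    n = len(full)

    # lagged[t, i] = temp[t - (l0 + i)]
    n_lags = l1 - l0 + 1
    lagged = np.full((n, n_lags), np.nan)
    for i, lag in enumerate(range(l0, l1 + 1)):
        if lag == 0:
            lagged[:, i] = s
        else:
            lagged[lag:, i] = s[:-lag]

    r_eval = ns_basis(lagged.ravel(), spec.var_spec).reshape(n, n_lags, spec.var_spec.df)
    c_eval = lag_basis_values(spec)  # (n_lags, lag_df)
    vals = np.einsum("tlj,lk->tjk", r_eval, c_eval).reshape(n, spec.n_columns)
    bad = ~np.isfinite(lagged).all(axis=1)
    vals[bad] = np.nan

    df = pd.DataFrame(vals, index=full, columns=spec.column_names()).reindex(temp.index)
    valid = df.index[df.notna().all(axis=1)]
    if len(valid) == 0:
        raise DataError(
            f"no day has a complete lag 0-{l1} history; series starts {temp.index.min().date()}"
        )
    return CrossBasisMatrix(values=df, spec=spec, valid_from=valid[0])
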