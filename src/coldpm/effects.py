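"""Reduction of fitted coefficients to cumulative exposure-response
summaries.

All contrasts are linear in the coefficients.  For temperatures ``x1``
versus ``x0`` the cumulative (lag 0-L) log odds ratio is ``a' beta``
with

    a_(j,k) = [R_j(x1) - R_j(x0)] * sum_l C_k(l)

so its variance is ``a' V a`` (delta method on the log scale; CIs are
exponentiated and therefore asymmetric around the OR).  Effect
modification by a pollutant at concentration ``p`` replaces ``beta`` by
the effective coefficients ``beta + p * gamma`` with covariance
``V_bb + p^2 V_gg + 2 p V_bg``, where ``gamma`` is the coefficient
vector of the crossbasis-by-pollutant interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import CrossBasisSpec, cumulative_lag_weights, lag_basis_values, ns_basis
from .clogit import FitResult
from .errors import ConfigError, DataError

__all__ = [
    "ExposureResponseCurve",
    "LagResponse",
    "ModificationSummary",
    "cumulative_contrast",
    "cumulative_curve",
    "modified_curve",
    "find_mmt",
    "mmt_from_fit",
    "extreme_cold_or",
    "or_from_fit",
    "pct_change_per_10",
    "lag_response",
    "summarize_modification",
]

Z95 = 1.959963984540054


@dataclass
class ExposureResponseCurve:
    """Cumulative temperature-mortality curve versus a reference."""

    temp_grid: np.ndarray
    log_or: np.ndarray
    se: np.ndarray
    ref_temp: float
    pm_level: float = None

    @property
    def odds_ratio(self):
        return np.exp(self.log_or)

    @property
    def ci_low(self):
        return np.exp(self.log_or - Z95 * self.se)

    @property
    def ci_high(self):
        return np.exp(self.log_or + Z95 * self.se)

    def at(self, temp):
        """(OR, lo, hi) at the grid point nearest ``temp``."""
        i = int(np.argmin(np.abs(self.temp_grid - temp)))
        return (float(np.exp(self.log_or[i])),
                float(np.exp(self.log_or[i] - Z95 * self.se[i])),
                float(np.exp(self.log_or[i] + Z95 * self.se[i])))


@dataclass
class LagResponse:
    """Lag-specific log odds ratios at a fixed temperature contrast."""

    lag_grid: np.ndarray
    log_or: np.ndarray
    se: np.ndarray
    x1: float
    x0: float
    pm_level: float = None


@dataclass
class ModificationSummary:
    """Cold-effect ORs at centered pollutant levels plus percent change
    per 10 ug/m3."""

    pollutant: str
    levels: dict              # name -> concentration (e.g. p10/p50/p90)
    or_at_level: dict         # name -> (OR, lo, hi)
    pct_per_10: tuple         # (pct, lo, hi)
    x1: float
    x0: float


def cumulative_contrast(spec: CrossBasisSpec, x1, x0) -> np.ndarray:
    """Contrast vector ``a`` such that ``a' beta`` is the cumulative
    log-OR at ``x1`` vs ``x0`` over the lag window."""
    r1 = ns_basis(float(x1), spec.var_spec)
    r0 = ns_basis(float(x0), spec.var_spec)
    c = cumulative_lag_weights(spec)
    return np.outer(r1 - r0, c).ravel()


def _cb_names(spec):
    return spec.column_names()


def _inter_names(spec, pollutant):
    return [f"{c}:{pollutant}" for c in spec.column_names()]


def _has_interaction(fit: FitResult, names):
    present = set(fit.colnames) | set(fit.dropped)
    return all(n in present for n in names)


def _effective(fit: FitResult, spec, pm_level=None, pollutant=None):
    """Effective crossbasis coefficients and covariance, optionally at a
    pollutant concentration."""
    cb = _cb_names(spec)
    beta = fit.coef(cb)
    v_bb = fit.vcov_block(cb)
    if pm_level is None:
        return beta, v_bb
    if pollutant is None:
        raise ConfigError("pollutant name required to evaluate a modified curve")
    inter = _inter_names(spec, pollutant)
    if not _has_interaction(fit, inter):
        raise ConfigError(
            f"fit has no crossbasis-by-{pollutant} interaction columns")
    gamma = fit.coef(inter)
    v_gg = fit.vcov_block(inter)
    v_bg = fit.vcov_block(cb, inter)
    p = float(pm_level)
    return beta + p * gamma, v_bb + p * p * v_gg + p * (v_bg + v_bg.T)


def _curve(beta, vcov, spec, ref_temp, grid, pm_level=None):
    grid = np.asarray(grid, dtype=float)
    if not (grid.min() - 1e-9 <= ref_temp <= grid.max() + 1e-9):
        raise ConfigError(f"reference {ref_temp} outside curve grid")
    r = ns_basis(grid, spec.var_spec) - ns_basis(float(ref_temp), spec.var_spec)
    c = cumulative_lag_weights(spec)
    A = np.einsum("nj,k->njk", r, c).reshape(len(grid), -1)
    log_or = A @ beta
    se = np.sqrt(np.maximum(np.einsum("ni,ij,nj->n", A, vcov, A), 0.0))
    return ExposureResponseCurve(temp_grid=grid, log_or=log_or, se=se,
                                 ref_temp=float(ref_temp), pm_level=pm_level)


def cumulative_curve(fit: FitResult, spec: CrossBasisSpec, ref_temp, grid):
    """Main-effect cumulative exposure-response curve."""
    beta, vcov = _effective(fit, spec)
    return _curve(beta, vcov, spec, ref_temp, grid)


def modified_curve(fit: FitResult, spec: CrossBasisSpec, pm_level, ref_temp, grid,
                   pollutant):
    """Cumulative curve at pollutant concentration ``pm_level``."""
    beta, vcov = _effective(fit, spec, pm_level, pollutant)
    return _curve(beta, vcov, spec, ref_temp, grid, pm_level=float(pm_level))


def find_mmt(curve: ExposureResponseCurve):
    """Minimum mortality temperature: argmin of the cumulative log-OR,
    ties broken toward the warmer temperature.  Reference-invariant."""
    if not np.all(np.isfinite(curve.log_or)):
        raise DataError("non-finite curve values in MMT search")
    lo = curve.log_or
    best = lo.min()
    idx = np.flatnonzero(lo <= best + 1e-12)
    return float(curve.temp_grid[idx.max()])


def mmt_from_fit(fit: FitResult, spec: CrossBasisSpec, search_range, step=0.1,
                 pm_level=None, pollutant=None):
    """MMT from a fit: dense-grid argmin over ``search_range``."""
    lo, hi = float(search_range[0]), float(search_range[1])
    grid = np.arange(lo, hi + step / 2, step)
    beta, vcov = _effective(fit, spec, pm_level, pollutant)
    curve = _curve(beta, vcov, spec, grid[0], grid)
    return find_mmt(curve)


def extreme_cold_or(curve: ExposureResponseCurve, temp):
    """Cumulative OR with 95% CI at the extreme-cold temperature
    (nearest grid point)."""
    return curve.at(temp)


def or_from_fit(fit: FitResult, spec: CrossBasisSpec, x1, x0,
                pm_level=None, pollutant=None):
    """Exact cumulative OR (95% CI) at ``x1`` vs ``x0``, optionally at a
    pollutant concentration."""
    beta, vcov = _effective(fit, spec, pm_level, pollutant)
    a = cumulative_contrast(spec, x1, x0)
    point = float(a @ beta)
    se = float(np.sqrt(max(a @ vcov @ a, 0.0)))
    return (np.exp(point), np.exp(point - Z95 * se), np.exp(point + Z95 * se))


def pct_change_per_10(fit: FitResult, spec: CrossBasisSpec, x1, x0, pollutant):
    """Percent change (95% CI) in the extreme-cold OR per 10 ug/m3 of
    the modifying pollutant: ``100 * (exp(10 * a' gamma) - 1)``."""
    inter = _inter_names(spec, pollutant)
    if not _has_interaction(fit, inter):
        raise ConfigError(f"fit has no crossbasis-by-{pollutant} interaction columns")
    gamma = fit.coef(inter)
    v_gg = fit.vcov_block(inter)
    a = cumulative_contrast(spec, x1, x0)
    delta = float(a @ gamma)
    se = float(np.sqrt(max(a @ v_gg @ a, 0.0)))
    pct = 100.0 * (np.exp(10.0 * delta) - 1.0)
    lo = 100.0 * (np.exp(10.0 * (delta - Z95 * se)) - 1.0)
    hi = 100.0 * (np.exp(10.0 * (delta + Z95 * se)) - 1.0)
    return pct, lo, hi


def lag_response(fit: FitResult, spec: CrossBasisSpec, x1, x0,
                 pm_level=None, pollutant=None) -> LagResponse:
    """Lag-specific log-ORs for the contrast ``x1`` vs ``x0``.

    Summing over integer lags reproduces the cumulative log-OR exactly.
    """
    beta, vcov = _effective(fit, spec, pm_level, pollutant)
    r = ns_basis(float(x1), spec.var_spec) - ns_basis(float(x0), spec.var_spec)
    C = lag_basis_values(spec)                       # (n_lags, lag_df)
    A = np.einsum("j,lk->ljk", r, C).reshape(C.shape[0], -1)
    log_or = A @ beta
    se = np.sqrt(np.maximum(np.einsum("li,ij,lj->l", A, vcov, A), 0.0))
    lags = np.arange(spec.lag_range[0], spec.lag_range[1] + 1)
    return LagResponse(lag_grid=lags, log_or=log_or, se=se,
                       x1=float(x1), x0=float(x0), pm_level=pm_level)


def summarize_modification(fit: FitResult, spec: CrossBasisSpec, pollutant,
                           levels: dict, x1, x0) -> ModificationSummary:
    """ORs at the centering concentrations and percent change per
    10 ug/m3, all for the contrast ``x1`` (extreme cold) vs ``x0`` (MMT)."""
    ors = {name: or_from_fit(fit, spec, x1, x0, pm_level=p, pollutant=pollutant)
           for name, p in levels.items()}
    pct = pct_change_per_10(fit, spec, x1, x0, pollutant)
    return ModificationSummary(pollutant=pollutant, levels=dict(levels),
                               or_at_level=ors, pct_per_10=pct,
                               x1=float(x1), x0=float(x0))
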