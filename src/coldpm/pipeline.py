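"""End-to-end analysis orchestration.

``run_analysis`` wires the full chain for one pollutant: resolve spline
specifications from the observed data, build the day-level covariates
and the time-stratified case-crossover design, maximise the conditional
likelihood, and reduce the fit to the reported quantities — the
cumulative temperature-mortality curve, the minimum mortality
temperature (MMT), the extreme-cold OR (1st temperature percentile vs
MMT) at the low/median/high pollutant centering levels, and the percent
change in the extreme-cold OR per 10 ug/m3 of pollutant.

``run_stratified`` repeats the fit within population subgroups and
``run_sensitivity`` over a battery of specification variants (maximum
lag, knot placement, RH degrees of freedom, ozone adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import CrossBasisSpec, build_crossbasis, lag_basis_knots
from .casecrossover import SUBGROUP_COLS, DayCovariates, build_design
from .clogit import FitResult, conditional_logistic_fit
from .effects import (ModificationSummary, cumulative_curve, find_mmt,
                      lag_response, modified_curve, or_from_fit,
                      pct_change_per_10, summarize_modification)
from .errors import ColdPMError, ConfigError, DataError

logger = logging.getLogger("coldpm")

__all__ = ["AnalysisConfig", "ReportBundle", "load_exposures", "load_deaths",
           "summarize_data", "run_analysis", "run_stratified",
           "run_sensitivity", "format_est"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Specification of one model fit.

    Defaults mirror the main analysis: lag 0-12 crossbasis with 3 df
    (temperature) x 4 df (lag), natural spline with 3 df for the RH
    moving average, pollutant centering at the 10th/50th/90th
    percentiles, extreme cold at the 1st temperature percentile.
    """

    pollutant: str = "pm1"
    max_lag: int = 12
    var_df: int = 3
    lag_df: int = 4
    rh_df: int = 3
    season_months: tuple = (11, 12, 1, 2)
    centering_percentiles: tuple = (10.0, 50.0, 90.0)
    extreme_percentile: float = 1.0
    mmt_grid_step: float = 0.1
    adjust_ozone: bool = False
    var_knots: tuple = None      # explicit temperature knots (else quantile rule)
    var_knot_percentiles: tuple = None  # alternative quantile positions for them
    lag_knots: tuple = None      # explicit lag knots (else log-spaced rule)
    interaction: bool = True
    robust: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.max_lag < 1:
            raise ConfigError("max_lag must be >= 1")
        for p in (*self.centering_percentiles, self.extreme_percentile):
            if not 0 < p < 100:
                raise ConfigError(f"percentile {p} outside (0, 100)")
        if self.pollutant not in ("pm1", "pm25"):
            raise ConfigError(f"unknown pollutant {self.pollutant!r}")

    @property
    def lag_range(self):
        return (0, self.max_lag)


@dataclass
class ReportBundle:
    """Everything one analysis run reports, traceable to its fit."""

    fit_id: str
    config: AnalysisConfig
    fit: FitResult
    spec: CrossBasisSpec
    percentiles: dict            # temp p1, pollutant p10/p50/p90, ranges
    mmt: float
    main_curve: object
    modified_curves: dict        # level name -> ExposureResponseCurve
    modification: ModificationSummary
    lag_pattern: object
    accounting: dict

    @property
    def extreme_cold_or(self):
        """(OR, lo, hi) at the median centering level."""
        return self.modification.or_at_level["p50"]

    @property
    def pct_per_10(self):
        return self.modification.pct_per_10


def _read_csv(path):
    try:
        return pd.read_csv(path, parse_dates=["date"])
    except (ValueError, OSError, pd.errors.ParserError) as e:
        raise DataError(f"cannot read {path}: {e}")


def load_exposures(path) -> pd.DataFrame:
    df = _read_csv(path)
    need = {"date", "temp_c", "rh_pct", "pm1", "pm25"}
    missing = need - set(df.columns)
    if missing:
        raise DataError(f"exposures file lacks columns: {sorted(missing)}")
    return df


def load_deaths(path) -> pd.DataFrame:
    df = _read_csv(path)
    if "date" not in df.columns:
        raise DataError("deaths file lacks a date column")
    if "n_deaths" not in df.columns:
        df["n_deaths"] = 1
    return df


def summarize_data(deaths: pd.DataFrame, exposures: pd.DataFrame,
                   season_months=(11, 12, 1, 2)) -> dict:
    """Descriptive table: subgroup counts/percentages and the
    25th/50th/75th percentiles of temperature and pollutants over the
    cold-season days."""
    if deaths.empty or exposures.empty:
        raise DataError("empty input to summarize_data")
    deaths = deaths.copy()
    deaths["date"] = pd.to_datetime(deaths["date"])
    in_season = deaths["date"].dt.month.isin(season_months)
    d = deaths[in_season]
    total = int(d["n_deaths"].sum())
    groups = {}
    for col in SUBGROUP_COLS:
        if col not in d.columns:
            continue
        cnt = d.groupby(col, dropna=False)["n_deaths"].sum()
        groups[col] = {str(k): {"n": int(v), "pct": round(100.0 * v / total, 2)}
                       for k, v in cnt.items()}
    env = {}
    e = exposures.copy()
    e["date"] = pd.to_datetime(e["date"])
    ea = e[e["date"].dt.month.isin(season_months)]
    for col in ("temp_c", "pm1", "pm25"):
        if col in ea.columns:
            q = np.percentile(ea[col].dropna(), [25, 50, 75], method="linear")
            env[col] = {"p25": float(q[0]), "p50": float(q[1]), "p75": float(q[2])}
    return {"n_deaths": total, "subgroups": groups, "environment": env}


def _resolve_spec(temps_analysis, config: AnalysisConfig) -> CrossBasisSpec:
    lag_knots = config.lag_knots
    if lag_knots is None:
        lag_knots = lag_basis_knots(config.lag_range, config.lag_df)
    var_knots = config.var_knots
    if var_knots is None and config.var_knot_percentiles is not None:
        var_knots = tuple(np.percentile(np.asarray(temps_analysis, float),
                                        config.var_knot_percentiles, method="linear"))
    return CrossBasisSpec.from_data(
        temps_analysis, var_df=config.var_df, lag_range=config.lag_range,
        lag_df=config.lag_df, var_knots=var_knots, lag_knots=lag_knots)


def _percentiles(temps_analysis, pol_analysis, config: AnalysisConfig) -> dict:
    t = np.asarray(temps_analysis, float)
    p = np.asarray(pol_analysis, float)
    lo, med, hi = config.centering_percentiles
    return {
        "temp_p1": float(np.percentile(t, config.extreme_percentile, method="linear")),
        "temp_min": float(t.min()),
        "temp_max": float(t.max()),
        "temp_p99": float(np.percentile(t, 99, method="linear")),
        "p10": float(np.percentile(p, lo, method="linear")),
        "p50": float(np.percentile(p, med, method="linear")),
        "p90": float(np.percentile(p, hi, method="linear")),
    }


def run_analysis(deaths: pd.DataFrame, exposures: pd.DataFrame,
                 config: AnalysisConfig, fit_id: str = "main") -> ReportBundle:
    """Fit one pollutant's model and reduce it to reported quantities.

    The MMT is located on the main-effect curve evaluated at the median
    pollutant level and then used as the common reference for the
    low/median/high centering levels.
    """
    exp = exposures.copy()
    exp["date"] = pd.to_datetime(exp["date"])
    exp = exp.set_index("date").sort_index()
    analysis_mask = exp.index.month.isin(config.season_months)
    temps_a = exp.loc[analysis_mask, "temp_c"].dropna().to_numpy()
    pol_a = exp.loc[analysis_mask, config.pollutant].dropna().to_numpy()
    if temps_a.size == 0:
        raise DataError("no cold-season exposure days")
    spec = _resolve_spec(temps_a, config)
    pcts = _percentiles(temps_a, pol_a, config)

    cb = build_crossbasis(exp["temp_c"], spec)
    day_cov = DayCovariates.assemble(
        exp, cb, config.pollutant, rh_df=config.rh_df,
        lag_range=config.lag_range, adjust_ozone=config.adjust_ozone,
        analysis_dates=exp.index[analysis_mask])
    design = build_design(deaths, day_cov, season_months=config.season_months,
                          interaction=config.interaction)
    fit = conditional_logistic_fit(design, {"robust": config.robust})
    logger.info("fit %s: %d strata (%.0f weighted cases), %d iters, loglik %.2f",
                fit_id, fit.n_strata, fit.n_weighted_cases, fit.n_iter, fit.loglik)

    total_in = int(pd.to_datetime(deaths["date"]).dt.month.isin(config.season_months)
                   .mul(deaths["n_deaths"] if "n_deaths" in deaths else 1).sum())
    accounting = {
        "input_cold_season_deaths": total_in,
        "used_deaths": int(fit.n_weighted_cases),
        "dropped_deaths": design.dropped_weight,
        "dropped_strata": design.n_dropped_strata,
        "drop_reasons": design.drop_reasons,
    }
    if accounting["used_deaths"] + accounting["dropped_deaths"] != total_in:
        raise DataError("death accounting failed: used + dropped != input")

    step = config.mmt_grid_step
    grid = np.arange(pcts["temp_min"], pcts["temp_max"] + step / 2, step)
    mmt_grid = grid[grid >= pcts["temp_p1"] - 1e-9]
    ref0 = float(mmt_grid[0])
    if config.interaction:
        curve_for_mmt = modified_curve(fit, spec, pcts["p50"], ref0, mmt_grid,
                                       config.pollutant)
    else:
        curve_for_mmt = cumulative_curve(fit, spec, ref0, mmt_grid)
    mmt = find_mmt(curve_for_mmt)

    if config.interaction:
        main_curve = modified_curve(fit, spec, pcts["p50"], mmt, grid, config.pollutant)
        mod_curves = {name: modified_curve(fit, spec, pcts[name], mmt, grid,
                                           config.pollutant)
                      for name in ("p10", "p50", "p90")}
        modification = summarize_modification(
            fit, spec, config.pollutant,
            {name: pcts[name] for name in ("p10", "p50", "p90")},
            pcts["temp_p1"], mmt)
        lag_pat = lag_response(fit, spec, pcts["temp_p1"], mmt,
                               pm_level=pcts["p50"], pollutant=config.pollutant)
    else:
        main_curve = cumulative_curve(fit, spec, mmt, grid)
        o = or_from_fit(fit, spec, pcts["temp_p1"], mmt)
        modification = ModificationSummary(
            pollutant=config.pollutant, levels={"p50": float("nan")},
            or_at_level={"p50": o}, pct_per_10=(0.0, 0.0, 0.0),
            x1=pcts["temp_p1"], x0=mmt)
        mod_curves = {}
        lag_pat = lag_response(fit, spec, pcts["temp_p1"], mmt)

    return ReportBundle(fit_id=fit_id, config=config, fit=fit, spec=spec,
                        percentiles=pcts, mmt=mmt, main_curve=main_curve,
                        modified_curves=mod_curves, modification=modification,
                        lag_pattern=lag_pat, accounting=accounting)


def format_est(point, lo, hi, digits=1):
    return f"{point:.{digits}f} ({lo:.{digits}f}, {hi:.{digits}f})"


_STRATA_DEFS = {
    "sex": ("male", "female"),
    "age_group": ("<75", ">=75"),
    "education": ("middle_or_below", "above_middle"),
    "cause_class": ("cardiorespiratory", "other"),
}


def run_stratified(deaths: pd.DataFrame, exposures: pd.DataFrame,
                   config: AnalysisConfig, strata_defs=None) -> pd.DataFrame:
    """Independent fits per population subgroup.

    Returns a table of percent change per 10 ug/m3 (with 95% CI) per
    subgroup, formatted ``x.x (l.l, u.u)``.  Deaths with missing
    education are excluded only from the education rows.  Subgroups
    that cannot be fitted are marked missing and the run continues.
    """
    strata_defs = strata_defs or _STRATA_DEFS
    rows = []
    overall = run_analysis(deaths, exposures, config, fit_id="overall")
    rows.append({"factor": "overall", "level": "overall",
                 "n_deaths": overall.accounting["used_deaths"],
                 "pct_per_10": format_est(*overall.pct_per_10),
                 "fit_id": "overall"})
    for factor, levels in strata_defs.items():
        if factor not in deaths.columns:
            continue
        for level in levels:
            sub = deaths[deaths[factor] == level]
            fid = f"{factor}={level}"
            if sub.empty:
                rows.append({"factor": factor, "level": level, "n_deaths": 0,
                             "pct_per_10": None, "fit_id": fid})
                continue
            try:
                b = run_analysis(sub, exposures, config, fit_id=fid)
                rows.append({"factor": factor, "level": level,
                             "n_deaths": b.accounting["used_deaths"],
                             "pct_per_10": format_est(*b.pct_per_10),
                             "fit_id": fid})
            except ColdPMError as e:
                logger.warning("subgroup %s failed: %s", fid, e)
                rows.append({"factor": factor, "level": level, "n_deaths": 0,
                             "pct_per_10": None, "fit_id": fid})
    return pd.DataFrame(rows)


def default_sensitivity_variants(config: AnalysisConfig) -> dict:
    """The robustness battery: maximum lag 10-18, alternative knot
    placements, RH df 4, and ozone adjustment."""
    variants = {}
    for lag in range(10, 19):
        if lag != config.max_lag:
            variants[f"max_lag={lag}"] = replace(config, max_lag=lag, lag_knots=None)
    variants["rh_df=4"] = replace(config, rh_df=4)
    variants["var_knots=p25_p75"] = replace(config, var_knot_percentiles=(25.0, 75.0))
    variants["ozone_adjusted"] = replace(config, adjust_ozone=True)
    variants["lag_knots=equal"] = replace(
        config, lag_knots=tuple(np.linspace(0, config.max_lag, config.lag_df)[1:-1]))
    return variants


def run_sensitivity(deaths: pd.DataFrame, exposures: pd.DataFrame,
                    config: AnalysisConfig, variants: dict = None) -> pd.DataFrame:
    """Side-by-side extreme-cold OR and pct-per-10 across variants."""
    variants = dict(variants) if variants is not None else default_sensitivity_variants(config)
    if not variants:
        raise ConfigError("empty sensitivity variant list")
    all_runs = {"base": config, **variants}
    rows = []
    for name, cfg in all_runs.items():
        try:
            b = run_analysis(deaths, exposures, cfg, fit_id=f"sens:{name}")
            rows.append({"variant": name,
                         "mmt": round(b.mmt, 1),
                         "extreme_cold_or": format_est(*b.extreme_cold_or, digits=2),
                         "pct_per_10": format_est(*b.pct_per_10),
                         "fit_id": b.fit_id})
        except ColdPMError as e:
            logger.warning("sensitivity variant %s failed: %s", name, e)
            rows.append({"variant": name, "mmt": None, "extreme_cold_or": None,
                         "pct_per_10": None, "fit_id": f"sens:{name}"})
    return pd.DataFrame(rows)
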