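"""Time-stratified case-crossover design assembly.

Each death day is a case; its referents are the other days of the same
calendar month and year falling on the same weekday (bidirectional
selection, 3-4 referents per case).  Deaths sharing region, date and
analysis subgroup are aggregated into one stratum with an integer
weight, which leaves the conditional-logistic likelihood unchanged while
shrinking the design by orders of magnitude.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import CrossBasisMatrix, SplineSpec, moving_average, ns_basis
from .errors import DataError

__all__ = ["Stratum", "DesignTable", "referent_days", "build_design", "DayCovariates"]

SUBGROUP_COLS = ["sex", "age_group", "education", "cause_class"]


@dataclass(frozen=True)
class Stratum:
    """One case day with its time-stratified referent days."""

    region: str
    case_date: dt.date
    referent_dates: tuple
    weight: int

    def __post_init__(self):
        if self.case_date in self.referent_dates:
            raise DataError("case date cannot be its own referent")
        if self.weight < 1:
            raise DataError("stratum weight must be a positive integer")


def referent_days(case_date) -> list:
    """All days of the same calendar month and year sharing the weekday
    of ``case_date``, excluding the case day itself, ascending.

    Proleptic-Gregorian calendar, ISO weekday convention.
    """
    ts = pd.Timestamp(case_date)
    month_days = pd.date_range(ts.replace(day=1), ts.replace(day=ts.days_in_month), freq="D")
    return [d.date() for d in month_days if d.weekday() == ts.weekday() and d != ts.normalize()]


@dataclass
class DayCovariates:
    """Per-day regressors shared by every stratum touching that day.

    ``table`` is indexed by date and holds the crossbasis columns, the
    RH-spline columns, the PM moving-average column (named after the
    pollutant) and any extra adjustment columns.
    """

    table: pd.DataFrame
    crossbasis_cols: list
    rh_cols: list
    pm_col: str
    extra_cols: list = field(default_factory=list)

    @classmethod
    def assemble(cls, exposures: pd.DataFrame, crossbasis: CrossBasisMatrix,
                 pollutant: str, rh_df: int = 3, lag_range=(0, 12),
                 adjust_ozone: bool = False, analysis_dates=None):
        """Join day-level regressors: crossbasis rows, a natural-spline
        expansion of the lag 0-12 RH moving average (knots from its
        observed quantiles on analysis days), the lag 0-12 PM moving
        average, and optionally the ozone moving average."""
        exp = exposures.set_index("date") if "date" in exposures.columns else exposures
        exp = exp.sort_index()
        rh_ma = moving_average(exp["rh_pct"], lag_range)
        pm_ma = moving_average(exp[pollutant], lag_range)
        ref_dates = rh_ma.index if analysis_dates is None else pd.DatetimeIndex(analysis_dates)
        rh_obs = rh_ma.reindex(ref_dates).dropna()
        if rh_obs.empty:
            raise DataError("no analysis day has a complete RH lag history")
        rh_spec = SplineSpec.from_quantiles(rh_obs.to_numpy(), rh_df)
        rh_cols = [f"rh_ns_{i}" for i in range(rh_df)]
        rh_mat = pd.DataFrame(ns_basis(rh_ma.to_numpy(), rh_spec),
                              index=rh_ma.index, columns=rh_cols)
        parts = [crossbasis.values, rh_mat, pm_ma.rename(pollutant)]
        extra = []
        if adjust_ozone:
            if "ozone" not in exp.columns:
                raise DataError("ozone adjustment requested but no ozone column")
            parts.append(moving_average(exp["ozone"], lag_range).rename("ozone_ma"))
            extra = ["ozone_ma"]
        table = pd.concat(parts, axis=1)
        return cls(table=table, crossbasis_cols=list(crossbasis.values.columns),
                   rh_cols=rh_cols, pm_col=pollutant, extra_cols=extra)


@dataclass
class DesignTable:
    """Stacked (stratum x day) regression rows for the conditional fit.

    Column order: crossbasis, RH spline, PM moving average, interaction
    (crossbasis x PM), extras.  Exactly one ``y = 1`` row per stratum;
    all rows of a stratum share its weight.
    """

    X: np.ndarray
    y: np.ndarray
    stratum_ids: np.ndarray
    weights: np.ndarray
    colnames: list
    terms: dict
    strata: list
    n_dropped_strata: int = 0
    dropped_weight: int = 0
    drop_reasons: dict = field(default_factory=dict)


def _aggregate_deaths(deaths: pd.DataFrame, by_subgroup: bool):
    cols = ["region", "date"] + (SUBGROUP_COLS if by_subgroup else [])
    cols = [c for c in cols if c in deaths.columns]
    if "n_deaths" in deaths.columns:
        agg = deaths.groupby(cols, dropna=False, observed=True)["n_deaths"].sum().reset_index()
    else:
        agg = deaths.groupby(cols, dropna=False, observed=True).size().rename("n_deaths").reset_index()
    return agg[agg["n_deaths"] > 0]


def build_design(deaths: pd.DataFrame, day_cov: DayCovariates,
                 season_months=(11, 12, 1, 2), by_subgroup: bool = False,
                 interaction: bool = True) -> DesignTable:
    """Assemble the case-crossover design table.

    Deaths are aggregated by (region, date[, subgroup]) into weighted
    strata; each stratum contributes one row per case/referent day with
    that day's covariates, the PM moving average, and (optionally) the
    crossbasis-by-PM interaction columns built from the raw, uncentered
    PM value.  Strata touching any day with a missing covariate are
    dropped whole and counted.
    """
    deaths = deaths.copy()
    deaths["date"] = pd.to_datetime(deaths["date"])
    in_season = deaths["date"].dt.month.isin(season_months)
    deaths = deaths[in_season]
    if deaths.empty:
        raise DataError("no deaths within the cold-season months")
    agg = _aggregate_deaths(deaths, by_subgroup)

    tab = day_cov.table
    cb_cols = day_cov.crossbasis_cols
    pm_col = day_cov.pm_col
    cov_cols = cb_cols + day_cov.rh_cols + [pm_col] + day_cov.extra_cols
    day_ok = tab[cov_cols].notna().all(axis=1)

    rows_X, rows_y, rows_sid, rows_w, strata = [], [], [], [], []
    n_dropped = 0
    dropped_weight = 0
    reasons = {"outside_exposures": 0, "missing_covariate": 0}
    sid = 0
    # cache referent lists and day validity per unique date
    ref_cache = {}
    for rec in agg.itertuples(index=False):
        case_date = pd.Timestamp(rec.date)
        key = case_date
        if key not in ref_cache:
            ref_cache[key] = [pd.Timestamp(d) for d in referent_days(case_date)]
        refs = ref_cache[key]
        days = [case_date] + refs
        w = int(rec.n_deaths)
        if any(d not in tab.index for d in days):
            n_dropped += 1
            dropped_weight += w
            reasons["outside_exposures"] += 1
            continue
        if not all(day_ok.loc[d] for d in days):
            n_dropped += 1
            dropped_weight += w
            reasons["missing_covariate"] += 1
            continue
        block = tab.loc[days, cov_cols].to_numpy(dtype=float)
        rows_X.append(block)
        rows_y.append(np.r_[1.0, np.zeros(len(refs))])
        rows_sid.append(np.full(len(days), sid))
        rows_w.append(np.full(len(days), w, dtype=float))
        strata.append(Stratum(region=str(getattr(rec, "region", "r0")),
                              case_date=case_date.date(),
                              referent_dates=tuple(d.date() for d in refs),
                              weight=w))
        sid += 1
    if not strata:
        raise DataError(
            f"zero usable strata ({n_dropped} dropped: {reasons})")

    X = np.vstack(rows_X)
    colnames = list(cov_cols)
    terms = {
        "crossbasis": cb_cols,
        "rh": day_cov.rh_cols,
        "pm": [pm_col],
        "extras": day_cov.extra_cols,
    }
    if interaction:
        pm_idx = colnames.index(pm_col)
        inter = X[:, :len(cb_cols)] * X[:, [pm_idx]]
        inter_cols = [f"{c}:{pm_col}" for c in cb_cols]
        # insert interactions before extras to keep the documented order
        n_main = len(cb_cols) + len(day_cov.rh_cols) + 1
        X = np.hstack([X[:, :n_main], inter, X[:, n_main:]])
        colnames = colnames[:n_main] + inter_cols + colnames[n_main:]
        terms["interaction"] = inter_cols

    return DesignTable(
        X=X, y=np.concatenate(rows_y), stratum_ids=np.concatenate(rows_sid),
        weights=np.concatenate(rows_w), colnames=colnames, terms=terms,
        strata=strata, n_dropped_strata=n_dropped, dropped_weight=dropped_weight,
        drop_reasons=reasons)
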