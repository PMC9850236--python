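"""Synthetic cold-season mortality study generator.

Generates daily environmental series (temperature, relative humidity,
PM1, PM2.5, ozone) and Poisson death counts for one or more cold
seasons, with a *known* cumulative temperature-lag-response surface and
a known linear pollutant interaction, so the full case-crossover DLNM
pipeline can be validated by parameter recovery.

The generative daily rate for subgroup cell ``g`` is

    lambda_g(t) = lambda0 * pi_g * exp( cb_t' beta*  +  theta * PM_ma(t)
                                        + PM_ma(t) * cb_t' gamma* * s_g )

where ``cb_t`` is the crossbasis row for day ``t`` built in the same
spline family the estimator uses (well-specified truth), ``PM_ma`` the
lag 0-12 moving average of the modifying pollutant, and ``s_g`` an
optional subgroup-specific interaction scale.  Conditioning counts on
their time-stratified totals yields exactly the conditional-logistic
model the estimator fits, so recovery is unbiased by construction.

Temperature follows an AR(1) process around a smooth seasonal mean
(two-harmonic cosine of the day of year); its defaults are calibrated
to the observed Shandong cold-season distribution (median 1.17 degC,
IQR -1.49 to 4.37) while letting early-November days reach past 19 degC
so that a minimum-mortality temperature of 18.5 degC lies inside the
observed range.  PM1/PM2.5 are correlated log-normals with AR(1)
persistence (multi-day pollution episodes) and a negative coupling to
temperature; medians/IQRs are calibrated to the observed values
(PM1 51.78, PM2.5 81.34 ug/m3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import CrossBasisSpec, build_crossbasis, moving_average, ns_basis
from .effects import cumulative_contrast
from .errors import CalibrationError, ConfigError, DataError

__all__ = [
    "TempParams",
    "PMParams",
    "RHParams",
    "TrueSurfaceSpec",
    "TrueSurface",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_weather",
    "simulate_pm",
    "calibrate_surface",
    "simulate_deaths",
    "simulate_study",
    "write_exposures",
    "write_deaths",
]

# Subgroup shares of cold-season deaths (observed registry margins).
DEFAULT_SUBGROUP_PROPS = {
    "sex": {"male": 0.5597, "female": 0.4403},
    "age_group": {"<75": 0.4410, ">=75": 0.5590},
    "education": {"middle_or_below": 0.8962, "above_middle": 0.0524,
                  "missing": 0.0514},
    "cause_class": {"cardiorespiratory": 0.6408, "other": 0.3592},
}


def _rng(seed, stream):
    """Deterministic child stream: PCG64 keyed by (seed, stream id)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class TempParams:
    """Seasonal AR(1) daily-mean temperature model (degC).

    The seasonal mean holds a warm autumn ``plateau`` through the
    lead-in, cools exponentially (e-folding ``tau_start`` days) to the
    deep-winter ``base``, and warms back toward ``end_level`` at the
    season end.  Anomalies are AR(1) with marginal standard deviation
    interpolated between ``sd_autumn`` (transition weeks) and
    ``sd_winter`` (deep winter) in proportion to the seasonal mean.
    The warm shoulder emulates the warm edge of a province-wide pooled
    district-day distribution, inside which the minimum-mortality
    temperature sits.
    """

    plateau: float = 17.0
    plateau_days: int = 8      # warm shoulder persists this far into November
    base: float = -1.8
    tau_start: float = 15.0
    end_level: float = 4.2
    tau_end: float = 22.0
    sd_winter: float = 3.3
    sd_autumn: float = 4.0
    ar: float = 0.7
    season_length: int = 119   # Nov 1 .. Feb 28

    @property
    def sd(self):
        """Representative (deep-winter) marginal anomaly sd."""
        return self.sd_winter

    def _days_since_nov1(self, dates: pd.DatetimeIndex) -> np.ndarray:
        years = np.where(dates.month >= 7, dates.year, dates.year - 1)
        nov1 = pd.to_datetime({"year": years, "month": 11, "day": 1})
        return (dates - pd.DatetimeIndex(nov1)).days.to_numpy()

    def seasonal_mean(self, dates: pd.DatetimeIndex) -> np.ndarray:
        d = np.maximum(self._days_since_nov1(dates) - self.plateau_days, 0)
        return (self.base
                + (self.plateau - self.base) * np.exp(-d / self.tau_start)
                + (self.end_level - self.base) * np.exp(-(self.season_length - d) / self.tau_end))

    def seasonal_sd(self, dates: pd.DatetimeIndex) -> np.ndarray:
        mu = self.seasonal_mean(dates)
        lo, hi = self.base, self.plateau
        frac = np.clip((mu - lo) / (hi - lo), 0.0, 1.0) if hi > lo else np.zeros(len(mu))
        return self.sd_winter + (self.sd_autumn - self.sd_winter) * frac


@dataclass(frozen=True)
class PMParams:
    """Log-normal pollutant model (ug/m3) with temperature coupling.

    log PM = log_median + coupling * (temp - seasonal mean temp) + u,
    u an AR(1) anomaly with marginal sd ``log_sd``; coupling <= 0 makes
    colder-than-usual days more polluted.
    """

    log_median: float
    log_sd: float
    coupling: float = -0.02
    ar: float = 0.9


@dataclass(frozen=True)
class RHParams:
    """Relative humidity: normal truncated to [0, 100] percent."""

    mean: float = 60.0
    sd: float = 15.0


@dataclass(frozen=True)
class TrueSurfaceSpec:
    """Targets the calibrated truth must reproduce.

    Either ``target_or_p1`` (cumulative OR at the 1st temperature
    percentile vs the MMT, evaluated at ``anchor`` pollutant level) with
    ``pct_per_10`` (percent modification per 10 ug/m3), or a pair of
    (OR at low level, OR at high level) via ``or_low``/``or_high`` at
    the ``level_percentiles`` of the simulated pollutant distribution.
    """

    true_mmt: float = 18.5
    target_or_p1: float = 1.83
    pct_per_10: float = 0.0
    or_low: float = None
    or_high: float = None
    level_percentiles: tuple = (10.0, 90.0)
    theta_pm: float = 3e-4     # linear log-rate per ug/m3 of the PM moving average
    lag_decay: float = 0.4     # exp(-decay * lag) target lag profile (front-loaded)
    warm_rise: float = 0.25    # warm-side rise of the J-shaped curve at the range max


@dataclass
class TrueSurface:
    """Calibrated truth: crossbasis coefficients and their summaries."""

    beta_star: np.ndarray
    gamma_star: np.ndarray
    theta_pm: float
    spec: CrossBasisSpec
    true_mmt: float
    p1_temp: float
    base_log_or: float        # a(P1, MMT)' beta_star
    delta_per_unit: float     # a(P1, MMT)' gamma_star
    anchor_pm: float
    info: dict = field(default_factory=dict)

    @property
    def pct_per_10(self):
        return 100.0 * (np.exp(10.0 * self.delta_per_unit) - 1.0)

    def true_or(self, pm_level=None):
        """True cumulative OR at P1 vs MMT, optionally at a pollutant level."""
        p = self.anchor_pm if pm_level is None else float(pm_level)
        return float(np.exp(self.base_log_or + (p - 0.0) * self.delta_per_unit))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cold-season mortality study."""

    n_seasons: int = 6
    season_months: tuple = (11, 12, 1, 2)
    start_year: int = 2013
    lead_in_days: int = 15
    baseline_rate: float = 400.0
    region: str = "r0"
    temp_params: TempParams = field(default_factory=TempParams)
    pm_params: dict = field(default_factory=lambda: {
        "pm1": PMParams(log_median=float(np.log(51.78)), log_sd=0.30),
        "pm25": PMParams(log_median=float(np.log(81.34)), log_sd=0.50),
    })
    pm_noise_corr: float = 0.8
    rh_params: RHParams = field(default_factory=RHParams)
    ozone_mean: float = 55.0
    ozone_sd: float = 18.0
    pollutant: str = "pm1"
    truth: TrueSurfaceSpec = field(default_factory=TrueSurfaceSpec)
    var_df: int = 3
    lag_df: int = 4
    lag_range: tuple = (0, 12)
    subgroup_props: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_SUBGROUP_PROPS.items()})
    subgroup_gamma_scale: dict = field(default_factory=dict)
    misspecified: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be positive")
        if not -1 < self.temp_params.ar < 1:
            raise ConfigError("temperature AR(1) coefficient must be in (-1, 1)")
        if self.temp_params.sd_winter < 0 or self.temp_params.sd_autumn < 0 or self.rh_params.sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        for name, p in self.pm_params.items():
            if p.log_sd < 0:
                raise ConfigError(f"{name} log-sd must be non-negative")
            if not -1 < p.ar < 1:
                raise ConfigError(f"{name} AR(1) coefficient must be in (-1, 1)")
        if self.lead_in_days < self.lag_range[1]:
            raise ConfigError(
                f"lead_in_days={self.lead_in_days} shorter than max lag {self.lag_range[1]}")

    def season_blocks(self):
        """Consecutive daily date ranges, one per season, each starting
        ``lead_in_days`` before 1 November."""
        blocks = []
        for s in range(self.n_seasons):
            y = self.start_year + s
            start = pd.Timestamp(y, 11, 1) - pd.Timedelta(days=self.lead_in_days)
            end = pd.Timestamp(y + 1, 3, 1) - pd.Timedelta(days=1)
            blocks.append(pd.date_range(start, end, freq="D"))
        return blocks

    def all_dates(self):
        return pd.DatetimeIndex(np.concatenate([b.values for b in self.season_blocks()]))

    def is_analysis_day(self, dates):
        return pd.DatetimeIndex(dates).month.isin(self.season_months)


def _ar1(rng, mean, marginal_sd, ar, n_blocks_lengths):
    """AR(1) anomalies with given marginal sd, restarted per block."""
    out = []
    pos = 0
    for n in n_blocks_lengths:
        z = rng.standard_normal(n)
        u = np.empty(n)
        if marginal_sd == 0:
            u[:] = 0.0
        else:
            u[0] = marginal_sd * z[0]
            innov_sd = marginal_sd * np.sqrt(1 - ar * ar)
            for t in range(1, n):
                u[t] = ar * u[t - 1] + innov_sd * z[t]
        out.append(mean[pos:pos + n] + u if mean is not None else u)
        pos += n
    return np.concatenate(out)


def simulate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Daily temperature, relative humidity and ozone for every season
    block (reproducible under the configured seed)."""
    dates = config.all_dates()
    lengths = [len(b) for b in config.season_blocks()]
    tp = config.temp_params
    mu = tp.seasonal_mean(dates)
    sd_t = tp.seasonal_sd(dates)
    e = _ar1(_rng(config.seed, 1), None, 1.0, tp.ar, lengths)
    temp = mu + sd_t * e

    rhp = config.rh_params
    rng_rh = _rng(config.seed, 2)
    if rhp.sd == 0:
        rh = np.full(len(dates), float(np.clip(rhp.mean, 0, 100)))
    else:
        from scipy.stats import truncnorm
        a, b = (0 - rhp.mean) / rhp.sd, (100 - rhp.mean) / rhp.sd
        rh = truncnorm.rvs(a, b, loc=rhp.mean, scale=rhp.sd,
                           size=len(dates), random_state=rng_rh)

    rng_oz = _rng(config.seed, 3)
    ozone = np.maximum(rng_oz.normal(config.ozone_mean, config.ozone_sd, len(dates)), 1.0)

    return pd.DataFrame({"date": dates, "region": config.region,
                         "temp_c": temp, "rh_pct": rh, "ozone": ozone})


def simulate_pm(config: SimulationConfig, temp: pd.Series) -> pd.DataFrame:
    """Correlated log-normal PM1/PM2.5 series driven by temperature.

    ``temp`` must be indexed by the simulation dates.  The log-scale
    noise of the two pollutants shares correlated innovations
    (``pm_noise_corr``) so the size fractions track each other; no hard
    PM1 <= PM2.5 constraint is imposed.
    """
    dates = pd.DatetimeIndex(temp.index)
    lengths = [len(b) for b in config.season_blocks()]
    if sum(lengths) != len(dates):
        lengths = [len(dates)]
    mu_season = config.temp_params.seasonal_mean(dates)
    anomaly = temp.to_numpy() - mu_season

    names = list(config.pm_params)
    rho = config.pm_noise_corr
    rng = _rng(config.seed, 4)
    n = len(dates)
    z = rng.standard_normal((n, len(names)))
    if len(names) == 2:
        z[:, 1] = rho * z[:, 0] + np.sqrt(max(1 - rho * rho, 0.0)) * z[:, 1]
    out = {}
    for i, name in enumerate(names):
        p = config.pm_params[name]
        u = np.empty(n)
        pos = 0
        for ln in lengths:
            zz = z[pos:pos + ln, i]
            if p.log_sd == 0:
                u[pos:pos + ln] = 0.0
            else:
                u[pos] = p.log_sd * zz[0]
                innov = p.log_sd * np.sqrt(1 - p.ar * p.ar)
                for t in range(1, ln):
                    u[pos + t] = p.ar * u[pos + t - 1] + innov * zz[t]
            pos += ln
        out[name] = np.exp(p.log_median + p.coupling * anomaly + u)
    return pd.DataFrame(out, index=dates)


def _constrained_lsq(M, g, A, b):
    """argmin ||M w - g||^2 subject to A w = b (KKT system)."""
    p = M.shape[1]
    k = A.shape[0]
    kkt = np.zeros((p + k, p + k))
    kkt[:p, :p] = 2 * M.T @ M
    kkt[:p, p:] = A.T
    kkt[p:, :p] = A
    rhs = np.r_[2 * M.T @ g, b]
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as e:
        raise CalibrationError(f"degenerate calibration system: {e}")
    return sol[:p]


def _unit_shape(spec: CrossBasisSpec, true_mmt, p1_temp, grid_step=0.1,
                warm_rise=0.25):
    """Variable-dimension coefficient vector with cumulative-curve
    argmin at ``true_mmt`` and unit contrast between P1 and the MMT.

    The target shape is J-shaped: quadratic rise toward cold reaching 1
    at P1, and a smaller quadratic rise (``warm_rise`` at the warm
    boundary) above the MMT, so the minimum is a genuine interior
    minimum rather than a flat shoulder.
    """
    b0, b1 = spec.var_spec.boundary_knots
    if not (b0 < true_mmt < b1):
        raise CalibrationError(
            f"true MMT {true_mmt} outside the observed temperature range ({b0:.2f}, {b1:.2f})")
    if not (b0 <= p1_temp < true_mmt):
        raise CalibrationError(
            f"P1 temperature {p1_temp:.2f} must lie below the MMT inside the range")
    grid = np.arange(b0, b1 + grid_step / 2, grid_step)
    R = ns_basis(grid, spec.var_spec)
    cold = np.clip((true_mmt - grid) / (true_mmt - p1_temp), 0, None) ** 2
    warm = warm_rise * (np.clip(grid - true_mmt, 0, None) / max(b1 - true_mmt, 1e-6)) ** 2
    g = cold + warm
    h = 1e-4
    d_mmt = (ns_basis(true_mmt + h, spec.var_spec) - ns_basis(true_mmt - h, spec.var_spec)) / (2 * h)
    contrast = ns_basis(float(p1_temp), spec.var_spec) - ns_basis(float(true_mmt), spec.var_spec)
    A = np.vstack([d_mmt, contrast])
    w = _constrained_lsq(R, g, A, np.array([0.0, 1.0]))
    f = R @ w
    argmin_t = grid[int(np.flatnonzero(f <= f.min() + 1e-12).max())]
    if abs(argmin_t - true_mmt) > max(2 * grid_step, 0.05):
        raise CalibrationError(
            f"cannot place the curve minimum at {true_mmt} degC: the closest "
            f"attainable argmin in this spline family is {argmin_t:.2f} degC")
    return w


def _lag_profile(spec: CrossBasisSpec, decay):
    """Lag-dimension coefficients: front-loaded exp(-decay*lag) profile
    normalised so the cumulative lag weight is one."""
    from .basis import cumulative_lag_weights, lag_basis_values
    C = lag_basis_values(spec)
    lags = np.arange(spec.lag_range[0], spec.lag_range[1] + 1, dtype=float)
    target = np.exp(-decay * lags)
    target = target / target.sum()
    c = cumulative_lag_weights(spec)
    return _constrained_lsq(C, target, c[None, :], np.array([1.0]))


def calibrate_surface(target_or_p1, pct_per_10, true_mmt, basis_meta: CrossBasisSpec,
                      p1_temp, anchor_pm=0.0, or_levels=None, theta_pm=3e-4,
                      lag_decay=0.4, warm_rise=0.25) -> TrueSurface:
    """Solve for crossbasis coefficients reproducing the requested
    cumulative cold effect and its pollutant modification.

    ``beta_star`` is proportional to a fixed shape vector (argmin of the
    implied cumulative curve at ``true_mmt``) scaled so the cumulative
    OR at P1 vs MMT equals ``target_or_p1`` at pollutant level
    ``anchor_pm``; ``gamma_star`` shares the shape, scaled so
    ``a' gamma = log(1 + pct_per_10/100) / 10``.  Alternatively
    ``or_levels = ((p_low, or_low), (p_high, or_high))`` pins the
    modified OR at two pollutant concentrations exactly.
    """
    spec = basis_meta
    w1 = _unit_shape(spec, float(true_mmt), float(p1_temp), warm_rise=warm_rise)
    u = _lag_profile(spec, lag_decay)

    if or_levels is not None:
        (p_lo, or_lo), (p_hi, or_hi) = or_levels
        if not (or_lo > 0 and or_hi > 0 and p_hi != p_lo):
            raise CalibrationError("invalid OR levels for calibration")
        delta = float(np.log(or_hi / or_lo) / (p_hi - p_lo))
        base = float(np.log(or_lo) - p_lo * delta)
        anchor = 0.0
    else:
        if target_or_p1 <= 0:
            raise CalibrationError("target OR must be positive")
        delta = float(np.log1p(pct_per_10 / 100.0) / 10.0)
        base = float(np.log(target_or_p1) - anchor_pm * delta)
        anchor = float(anchor_pm)

    beta_star = np.outer(base * w1, u).ravel()
    gamma_star = np.outer(delta * w1, u).ravel()

    a = cumulative_contrast(spec, p1_temp, true_mmt)
    if abs(a @ beta_star - base) > 1e-8 or abs(a @ gamma_star - delta) > 1e-8:
        raise CalibrationError("calibration round-trip failed beyond 1e-8")

    return TrueSurface(
        beta_star=beta_star, gamma_star=gamma_star, theta_pm=float(theta_pm),
        spec=spec, true_mmt=float(true_mmt), p1_temp=float(p1_temp),
        base_log_or=base, delta_per_unit=delta, anchor_pm=anchor,
        info={"target_or_p1": target_or_p1, "pct_per_10": pct_per_10,
              "or_levels": or_levels, "lag_decay": lag_decay,
              "warm_rise": warm_rise})


def _cell_table(config: SimulationConfig):
    """Cartesian subgroup cells with proportions and gamma scales."""
    factors = list(config.subgroup_props)
    cells = [({}, 1.0, 1.0)]
    for f in factors:
        new = []
        for labels, prop, scale in cells:
            for lvl, p in config.subgroup_props[f].items():
                s = config.subgroup_gamma_scale.get(f, {}).get(lvl, 1.0)
                new.append(({**labels, f: lvl}, prop * p, scale * s))
        cells = new
    return cells


def simulate_deaths(config: SimulationConfig, exposures: pd.DataFrame,
                    truth: TrueSurface, expanded: bool = False) -> pd.DataFrame:
    """Poisson death counts per analysis day and subgroup cell.

    Requires exposures to span at least ``max lag`` days before the
    first analysis day.  Returns aggregated records (date, region,
    n_deaths, subgroup labels) by default; ``expanded=True`` emits one
    row per death.
    """
    exp = exposures.set_index("date") if "date" in exposures.columns else exposures
    exp = exp.sort_index()
    cb = build_crossbasis(exp["temp_c"], truth.spec)
    pm_ma = moving_average(exp[config.pollutant], config.lag_range)

    dates = exp.index
    analysis = dates[config.is_analysis_day(dates)]
    first = analysis.min()
    if cb.values.loc[analysis].isna().any().any() or pm_ma.loc[analysis].isna().any():
        raise DataError(
            f"insufficient lead-in: first analysis day {first.date()} precedes the "
            f"first complete-lag-history day {cb.valid_from.date()}")

    cba = cb.values.loc[analysis].to_numpy()
    pma = pm_ma.loc[analysis].to_numpy()
    if config.misspecified:
        eta_temp, eta_int = _misspecified_eta(config, exp, analysis, truth)
    else:
        eta_temp = cba @ truth.beta_star
        eta_int = cba @ truth.gamma_star
    base_eta = eta_temp + truth.theta_pm * pma

    cells = _cell_table(config)
    rng = _rng(config.seed, 5)
    frames = []
    for labels, prop, scale in cells:
        lam = config.baseline_rate * prop * np.exp(base_eta + pma * eta_int * scale)
        counts = rng.poisson(lam)
        keep = counts > 0
        if not keep.any():
            continue
        df = pd.DataFrame({"date": analysis[keep], "region": config.region,
                           "n_deaths": counts[keep], **{k: v for k, v in labels.items()}})
        frames.append(df)
    if not frames:
        raise DataError("simulation produced zero deaths; baseline rate too low")
    deaths = pd.concat(frames, ignore_index=True).sort_values(
        ["date", "sex", "age_group", "education", "cause_class"]).reset_index(drop=True)
    if expanded:
        deaths = deaths.loc[deaths.index.repeat(deaths["n_deaths"])].assign(
            n_deaths=1).reset_index(drop=True)
    return deaths


def _misspecified_eta(config, exp, analysis, truth):
    """Quadratic-in-temperature truth outside the spline family: the
    log-rate is a direct double sum of q(temp[t-l]) * profile(l)."""
    l0, l1 = config.lag_range
    lags = np.arange(l0, l1 + 1)
    prof = np.exp(-truth.info.get("lag_decay", 0.4) * lags)
    prof = prof / prof.sum()
    scale = (truth.true_mmt - truth.p1_temp) ** 2
    temp = exp["temp_c"]

    def q(x):
        return truth.base_log_or * (truth.true_mmt - x) ** 2 / scale

    def qg(x):
        return truth.delta_per_unit * (truth.true_mmt - x) ** 2 / scale

    eta_t = np.zeros(len(analysis))
    eta_i = np.zeros(len(analysis))
    for i, d in enumerate(analysis):
        hist = temp.loc[d - pd.Timedelta(days=l1):d].to_numpy()[::-1][l0:l1 + 1]
        eta_t[i] = float(np.sum(q(hist) * prof))
        eta_i[i] = float(np.sum(qg(hist) * prof))
    ref = q(np.array([truth.true_mmt]))[0]
    return eta_t - ref, eta_i


@dataclass
class SimulatedStudy:
    """One simulated study: inputs, truth, and handy summaries."""

    exposures: pd.DataFrame
    deaths: pd.DataFrame
    truth: TrueSurface
    spec: CrossBasisSpec
    config: SimulationConfig
    p1_temp: float
    pm_percentiles: dict


def simulate_study(config: SimulationConfig, expanded: bool = False) -> SimulatedStudy:
    """End-to-end generation: weather, pollutants, calibrated truth,
    deaths.  The crossbasis family (knots from the observed cold-season
    temperature quantiles) is resolved from the simulated data itself,
    exactly as the estimator will re-derive it."""
    weather = simulate_weather(config)
    temp = weather.set_index("date")["temp_c"]
    pm = simulate_pm(config, temp)
    exposures = weather.assign(pm1=pm["pm1"].to_numpy(), pm25=pm["pm25"].to_numpy())

    is_analysis = config.is_analysis_day(exposures["date"])
    temps_a = exposures.loc[is_analysis, "temp_c"].to_numpy()
    spec = CrossBasisSpec.from_data(temps_a, var_df=config.var_df,
                                    lag_range=config.lag_range, lag_df=config.lag_df)
    p1 = float(np.percentile(temps_a, 1.0, method="linear"))
    pol = exposures.loc[is_analysis, config.pollutant].to_numpy()
    pcts = {f"p{int(q)}": float(np.percentile(pol, q, method="linear"))
            for q in (10, 50, 90)}

    t = config.truth
    if t.or_low is not None and t.or_high is not None:
        q_lo, q_hi = t.level_percentiles
        p_lo = float(np.percentile(pol, q_lo, method="linear"))
        p_hi = float(np.percentile(pol, q_hi, method="linear"))
        truth = calibrate_surface(None, None, t.true_mmt, spec, p1,
                                  or_levels=((p_lo, t.or_low), (p_hi, t.or_high)),
                                  theta_pm=t.theta_pm, lag_decay=t.lag_decay,
                                  warm_rise=t.warm_rise)
    else:
        anchor = pcts["p50"] if t.pct_per_10 != 0 else 0.0
        truth = calibrate_surface(t.target_or_p1, t.pct_per_10, t.true_mmt, spec,
                                  p1, anchor_pm=anchor, theta_pm=t.theta_pm,
                                  lag_decay=t.lag_decay, warm_rise=t.warm_rise)

    deaths = simulate_deaths(config, exposures, truth, expanded=expanded)
    return SimulatedStudy(exposures=exposures, deaths=deaths, truth=truth,
                          spec=spec, config=config, p1_temp=p1, pm_percentiles=pcts)


def write_exposures(exposures: pd.DataFrame, path):
    cols = ["date", "region", "temp_c", "rh_pct", "pm1", "pm25", "ozone"]
    out = exposures.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[cols].to_csv(path, index=False)


def write_deaths(deaths: pd.DataFrame, path):
    cols = ["date", "region", "n_deaths", "sex", "age_group", "education", "cause_class"]
    out = deaths.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[cols].to_csv(path, index=False)
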