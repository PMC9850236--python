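# coldpm

Cold-temperature mortality risk and its modification by fine
particulate matter (PM₁/PM₂.₅), estimated with a time-stratified
case-crossover design and a distributed lag non-linear model (DLNM) —
plus a calibrated synthetic-data generator so the whole pipeline is
validated by parameter recovery rather than by access to confidential
registry data.

## The problem and the model

Cold spells kill, with a delay: a cold day raises mortality for up to
two weeks. Airborne particulate matter may amplify that risk, and
smaller particles (PM₁) may amplify it more per unit mass than PM₂.₅.
Quantifying this interaction needs a design that removes slow
confounders (season, long-term trends, individual characteristics) and
a model that captures both the non-linearity and the lag structure of
the temperature effect.

Each death is its own stratum: the day of death is the *case day*, and
the other days of the same calendar month and year falling on the same
weekday are its *referent days* (time-stratified case-crossover,
bidirectional, 3–4 referents per case). Within a stratum the model is
the conditional logistic regression

```
logit P = α_stratum + cb(Temp) + ns(RH, 3 df) + PM + cb(Temp)·PM
```

where `cb(Temp)` is the DLNM crossbasis over lags 0–12 days — a tensor
product of a natural cubic spline in temperature (3 df) and a natural
cubic spline in lag (4 df) — `ns(RH, 3 df)` a natural spline of the
lag 0–12 moving average of relative humidity, and `PM` the lag 0–12
moving average of PM₁ or PM₂.₅ (one model set per pollutant). Stratum
constants `α` cancel in the conditional likelihood; deaths sharing a
day are aggregated into weighted strata, which leaves the likelihood
unchanged and makes a 300 000-death fit take about a second.

The fitted coefficients are reduced to:

* the cumulative exposure–response curve `exp(a(x, x₀)'β)` over
  lags 0–12, with delta-method CIs on the log scale;
* the **MMT** (minimum mortality temperature), the argmin of that
  curve;
* the **extreme-cold OR**, the cumulative OR at the 1st percentile of
  cold-season temperature versus the MMT, evaluated at the pollutant's
  10th/50th/90th percentile (centering levels) via the effective
  coefficients `β + p·γ`;
* the **percent change per 10 µg/m³**, `100·(exp(10·a'γ) − 1)`, from
  the interaction coefficients `γ`.

The synthetic generator simulates cold seasons (Nov–Feb) with an
AR(1)-around-seasonal-mean temperature, correlated log-normal
PM₁/PM₂.₅ coupled to temperature, and Poisson death counts whose
log-rate uses a *known* crossbasis surface calibrated to chosen targets
(e.g. OR 1.83 at P1 vs an MMT of 18.5 °C, +7.6 % per 10 µg/m³).
Conditioning the counts on their stratum totals gives exactly the
likelihood the estimator maximises, so recovery is unbiased by
construction and any failure is a bug.

## Worked example

```
$ python analysis/01_simulate.py
simulated 464357 deaths over 721 days; true OR 1.830 at P1 (-7.5 degC) vs MMT 18.5 degC, +7.6% per 10 ug/m3 PM1
$ python analysis/03_fit_main.py
MMT 18.01 degC (truth 18.5); extreme-cold OR 1.82 (1.73, 1.91) at the median PM1 level (truth 1.83)
$ python analysis/04_modification.py
pm1: extreme-cold OR 1.58 (1.46, 1.71) at low, 2.17 (1.94, 2.43) at high level; +8.4% per 10 ug/m3 (truth +7.6%)
pm25: extreme-cold OR 1.62 (1.52, 1.73) at low, 2.42 (2.16, 2.71) at high level; +3.2% per 10 ug/m3 (truth +2.6%)
```

Reading this: the generator planted a cumulative cold effect of 1.83
(deaths are 83 % more likely after a 13-day history at −7.5 °C than at
the minimum-mortality temperature) and a modification of +7.6 % per
10 µg/m³ PM₁. The pipeline, given only the simulated death records and
exposure series, recovers an OR of 1.82 (95 % CI 1.73–1.91), an MMT
half a degree from the truth, a cold effect that climbs from 1.58 on
clean days to 2.17 on polluted days, and a modification estimate of
+8.4 % (CI 4.0–13.1) — the truth well inside every interval.

`analysis/02_descriptives.py`, `05_stratified.py` and
`06_sensitivity.py` produce the descriptive table, the subgroup table
(the generator gives the elderly a stronger true interaction, and the
fits recover the ordering) and the robustness battery (maximum lag
10–18 days, alternative knots, RH df 4, ozone adjustment); tables land
in `results/`.

The same machinery is scriptable from a shell: `coldpm simulate`,
`coldpm summarize`, `coldpm fit`, `coldpm report`,
`coldpm sensitivity` (see `coldpm --help`).

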