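# Methods

## Design and likelihood

Every death defines a stratum: its case day plus the 3–4 same-weekday
days of the same calendar month and year (time-stratified,
bidirectional referent selection; proleptic-Gregorian calendar, ISO
weekdays). Because all deaths in a region share day-level exposures,
deaths are aggregated by (region, day, subgroup) into strata with an
integer weight; the weighted conditional-logistic likelihood

    l(β) = Σ_s w_s [ η_case(s) − log Σ_{d∈s} exp(η_d) ]

is exactly the likelihood of the per-death expansion (asserted to
1e−10 in the tests). Maximisation is Newton–Raphson from zero with
step-halving; columns are internally scaled to unit variance and the
score tolerance is 1e−8 per weighted case, since an absolute 1e−8 on a
score summing ~3×10⁵ weighted cases is below float64 resolution.
Covariance is the inverse observed information (a sandwich option
exists). Columns with no within-stratum variation anywhere (variance
< 1e−12 in every stratum) are unidentifiable — stratum constants
absorb them — and are dropped and reported.

## Bases

Natural cubic splines are built from a cubic B-spline design with the
natural constraint (zero second derivative at the boundary knots)
applied by post-multiplication with the null space of the constraint
matrix, and linear (first-order Taylor) extension beyond the
boundaries; the construction is validated against a truncated-power
basis oracle to 1e−8. Default knots: temperature dimension — df−1
internal knots at equally spaced quantiles of the observed cold-season
temperatures, boundaries at the observed min/max; lag dimension —
internal knots at equally spaced quantiles of log(lag+1), denser at
short lags; RH spline — quantiles of the observed RH moving average.

The temperature basis has no intercept (levels cancel within strata).
The lag basis *does* carry one: an intercept-free natural spline
vanishes identically at the left boundary, which would force every
fitted surface to zero effect on the exposure day itself — incompatible
with cold effects that appear on the first day of exposure and with
standard DLNM practice. With 3 temperature df × 4 lag df the
crossbasis has 12 columns; row t, column (j,k) is
Σ_l R_j(temp[t−l])·C_k(l), checked against a direct double loop to
1e−12 for every knot configuration in the sensitivity battery.

Missing exposure handling is conservative and symmetric: a missing day
makes every moving average and crossbasis row whose lag window touches
it missing, and any stratum containing an affected case *or* referent
day is dropped whole and counted. Every run asserts
input deaths = used + dropped.

## Reductions

All reported quantities are linear contrasts on the log scale. The
cumulative contrast vector is a_(j,k) = [R_j(x₁) − R_j(x₀)]·Σ_l C_k(l);
the cumulative log-OR is a'β with variance a'Va (delta method, CIs
exponentiated and therefore asymmetric). Modification by a pollutant
at concentration p uses effective coefficients β + p·γ with covariance
V_ββ + p²V_γγ + 2p·V_βγ; interaction columns are built from raw
(uncentered) PM, and centering happens only at prediction — the two
parameterisations give identical curves. The MMT is the argmin of the
cumulative curve on a 0.1 °C grid from the observed 1st percentile to
the observed maximum, ties broken toward the warmer temperature; it is
reference-invariant, located on the curve at the *median* pollutant
level, and then used as the common reference for all centering levels
(one MMT for all contrasts). Percent change per 10 µg/m³ is
100·(exp(10·a'γ) − 1); the identity
OR(p₂)/OR(p₁) = (1 + pct/100)^((p₂−p₁)/10) holds exactly and is
asserted on every fit. Percentiles use the linear-interpolation
quantile rule over the analysis-period days.

## Synthetic data

The generator's defaults are the study conditions: six cold seasons
(Nov 1–Feb 28/29, with 15 lead-in days from mid-October so the first
analysis day has a full lag history) in one region at 400 baseline
deaths/day (≈450 000 deaths).

**Temperature** is AR(1) (lag-1 autocorrelation 0.7) around a seasonal
mean that holds a warm autumn plateau (17 °C through early November),
cools exponentially (e-folding 15 days) to a deep-winter base of
−1.8 °C, and warms toward 4.2 °C by late February; anomaly sd is
3.3 °C in deep winter and 4.0 °C in the transition weeks. These values
were calibrated once so the cold-season marginal matches the observed
registry distribution (median 1.17 °C, IQR −1.49 to 4.37 °C) while the
observed maximum reliably exceeds 19 °C — the warm shoulder stands in
for the warm edge of a province-wide pooled district-day distribution,
inside which the minimum-mortality temperature (18.5 °C) must lie. The
generator does *not* reproduce the extreme cold tail of the pooled
registry (its P1 is ≈ −7.5 °C rather than −16.9 °C): truth calibration
is always relative to the simulated P1, so recovery checks are
unaffected, but absolute temperatures at the cold extreme are not
comparable to the registry's.

**Pollutants** are log-normal with medians/IQRs calibrated to the
registry (PM₁ 51.78, PM₂.₅ 81.34 µg/m³), a shared negative coupling to
the temperature anomaly (−0.02 per °C; colder-than-usual days are more
polluted — the registry reports no temperature–PM correlation, so this
is a free modelling choice), correlated log-scale noise between the
two size fractions (ρ = 0.8, no hard PM₁ ≤ PM₂.₅ constraint since each
pollutant enters its own model set), and AR(1) persistence 0.9 on the
log anomalies. The persistence emulates multi-day pollution episodes;
it also matters statistically, because the model's PM term is a 13-day
moving average, and the moving average of serially independent noise
would have almost no within-stratum variation left to identify γ.
**RH** is truncated-normal (60 ± 15 %, clipped to [0,100]) and ozone
is normal noise with no effect on mortality — both act only as
adjustment covariates.

**Truth calibration.** The true surface lives in the estimator's own
spline family (well-specified recovery; a quadratic out-of-family mode
exists for misspecification experiments but is not used for
acceptance). The variable-dimension coefficient vector is the
equality-constrained least-squares fit of a J-shaped target (quadratic
rise toward cold reaching the target log-OR at P1; a smaller quadratic
rise, 0.25 of the contrast by default, above the MMT) subject to zero
slope at the MMT and an exact cumulative contrast; the implied argmin
is verified on a grid and a calibration error is raised if the family
cannot place it (e.g. an MMT outside the observed range). The lag
profile is the constrained LS fit of a front-loaded exp(−0.4·lag)
shape normalised to unit cumulative weight. γ* shares the shape of β*,
scaled so a'γ = log(1 + pct/100)/10 — hence all modified curves share
one MMT — or, alternatively, so the modified ORs at two pollutant
percentiles hit prescribed values exactly. A linear PM main effect
(θ = 3×10⁻⁴ per µg/m³) is included so the PM main-effect column is
exercised. Death counts are Poisson per day × subgroup cell (cell
shares follow the registry margins; subgroup-specific interaction
scales are configurable), and conditioning on stratum totals
reproduces the fitted model exactly, which the tests verify with an
empirical rate-ratio oracle at ~10⁶ expected deaths.

**RNG.** One PCG64 generator per component (temperature, RH, ozone,
PM, deaths), each keyed deterministically by (seed, stream id); every
output is bit-reproducible under a fixed seed.

## Validation scenarios and problem sizes

Parameter-recovery scenarios calibrate the truth to the published
headline estimates (`coldpm.scenarios`): OR 1.83 at P1 vs MMT;
modified ORs 1.60/2.20 (PM₁) and 1.60/2.24 (PM₂.₅) at the 10th/90th
pollutant percentiles; +7.6 %/+2.6 % per 10 µg/m³; MMT 18.5 °C. The
default scenarios use 400 deaths/day. At that size one six-season
replicate estimates the extreme-cold log-OR with se ≈ 0.03, so the
test suite uses 20 replicates (mean within ±0.10 of truth, CI coverage
with a one-miss binomial allowance at n = 20) and the acceptance
script reports Monte-Carlo means over 10 replicates per target.

MMT localisation is different in kind: the cumulative curve is nearly
flat around its minimum (the attainable curvature at the minimum is
limited by the 3-df spline family itself), so the argmin carries far
more Monte-Carlo noise than any contrast. The MMT scenario is
therefore power-sized at 3 000 deaths/day — full registry scale
(≈2 000/day) with a 1.5× margin — where the per-replicate sd is
≈0.3 °C; at 400/day the per-replicate sd is ≈1 °C, which is why the
acceptance script reports the mean over 20 replicates for that target.
This is a property worth remembering when reading any single-study
MMT: at typical provincial sample sizes its uncertainty is measured in
degrees, not tenths.

## What passing tests do and do not show

The generator shares the estimator's spline family, one region, clean
exposures and Poisson counts. Passing recovery therefore demonstrates
correctness of the machinery — referent selection, design assembly,
likelihood, covariance, reductions — under a well-specified model. It
does not address exposure measurement error, spatial heterogeneity
across districts, overdispersion, harvesting/displacement, or
approximation error when the true surface is outside the spline family
(the misspecified mode exists precisely to explore that last question,
and the sensitivity battery probes robustness to the specification
choices the analyst controls).

## Known limitations

* One region (or a handful of independent ones); no spatial
  correlation and no two-stage pooling across regions.
* Wald/delta-method CIs throughout (1.96 quantile); no bootstrap.
* No penalisation or ridge fallback in the fitter: quasi-separated or
  aliased designs raise errors instead of being silently regularised.
* The descriptive module reports the records it is given; it does not
  attempt to reconcile bookkeeping discrepancies between a registry's
  totals and its category sums.
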