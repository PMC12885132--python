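# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and what the validation suite does and does not
demonstrate.

## Scientific setting

Wildfire smoke delivers fine particulate matter (PM2.5) in rare, intense,
multi-day episodes, quite unlike the smooth background of ambient PM2.5.
The package studies its association with preterm birth (gestational age
< 259 days, i.e. before 37 completed weeks) in cohorts where census-tract
daily wildfire-specific PM2.5 is linked to pregnancies through residential
history.  Gestational time is measured from conception: day 0 is conception,
gestational week *w* spans days [7w, 7w+6], and "exposure at the start of
week *w*" means days 0..7w−1, so an outcome week's own exposure never enters
its risk row.

## Exposure metrics

Per pregnancy, from the linked daily vector:

* **mean daily wildfire PM2.5** (µg/m³) over the exposure period;
* **smoke days**: days with concentration strictly > 0 (the stored value is
  exactly zero on non-smoke days, so no epsilon is needed), and days at or
  above the intensity thresholds 2.5, 5.0 and 10.0 µg/m³ — approximately the
  50th, 75th and 90th percentiles of smoke-day concentrations;
* **smoke waves**: maximal runs of consecutive smoke days at a threshold
  with length ≥ d for d ∈ {2, 3, 4}.  A wave of duration d is counted as
  "at least d consecutive days": one 5-day run contributes one wave at each
  of d = 2, 3, and ≥ 4.  This convention makes prevalence monotone
  non-increasing in duration, which matches how duration-graded wave
  prevalences behave in cohort descriptives; the alternative (mutually
  exclusive run-length bins) is a one-line change in `count_smoke_waves`
  and is exercised in the unit tests through the run-length oracle.
* **weekly and cumulative metrics**: smoke days within each gestational week
  0–35; cumulative mean and smoke-day / smoke-wave counts over days
  0..7w−1 for each week w.

Residential linkage takes the tract of residence on each pregnancy day from
the half-open residence intervals; gaps up to `max_gap = 7` days carry the
last tract forward, longer gaps are linkage errors naming the date.
Trimester windows are weeks 0–12, 13–26 and 27–delivery — a documented
convention, since trimester boundaries are not standardised to the day.

## Cohort construction

Inclusion keeps singleton live births with a parseable conception date,
conception within the study window, gestational age ≥ 154 days (22 weeks),
and conception at least 41 weeks (287 days) before the end of exposure
coverage.  The last rule removes *fixed cohort bias*: near the end of a
time-bounded exposure record, only short (preterm) pregnancies complete in
time to be observed, so including them would select on the outcome.  The
41-week rule precedes the window-upper check in the exclusion ledger because
the window's upper bound is derived from it.  Site-level exclusions drop
sites with fewer than 100 eligible births, more than 25% missingness in
primary-model covariates (both configurable), or a metadata flag for
outcome-dependent recruitment.

Person-period expansion produces one row per pregnancy and at-risk
gestational week 22..36: a preterm birth delivered in week w\* contributes
weeks 22..w\* with the event indicator 1 only at w\*; term births contribute
all fifteen weeks with event 0 (censoring at week 36).  Row counts satisfy
`min(GA // 7, 36) − 21` per pregnancy, asserted exactly in the tests.

## Models

**Pooled logistic regression** fits
`logit P(event) = α_w + β·X(w) + γ'Z + b_site` on the person-period rows.
Because each row is a Bernoulli trial conditional on reaching its week, exp β
is the conditional (discrete-time hazard) odds ratio per unit of cumulative
exposure.  Covariate sets:

* *model 1*: infant sex, age at delivery (natural cubic spline, 3 df), race,
  Hispanic ethnicity, census-tract poverty rate, season of conception, birth
  year (spline, 4 df), and a 2-d thin-plate spatial smooth (10 df) of the
  residence coordinates (first recorded residence) to absorb geographic
  confounding;
* *model 2*: model 1 plus parity, prepregnancy BMI, tobacco use, alcohol
  consumption, gestational-age determination method, and education;
* *none*: intercept, week indicators and exposure only — used in simulation
  studies whose generator has no covariate effects, where adjustment would
  only spend runtime and degrees of freedom.

Reference levels are race = White, season = winter, parity = 0; the tests
verify that re-parameterising the reference leaves the exposure estimate
unchanged.  Week indicators use interval grouping: an event-free week's
indicator is unidentified (its MLE diverges), so adjacent weeks are merged
until every indicator bin contains at least one event.  At realistic cohort
sizes every week has events and the grouping is the identity map.

**Random intercepts** are integrated out by adaptive Gauss–Hermite
quadrature: per site the integrand is recentred at the conditional mode and
rescaled by the conditional curvature before applying a 7-node Hermite rule
(1 node = the Laplace approximation; both are available behind
`ModelSpec.method`).  The optimiser alternates re-adapting the grid with
maximising the fixed-grid likelihood by L-BFGS using the analytic gradient,
until the relative log-likelihood change falls below 1e-8.  Standard errors
come from the numerically differentiated Hessian of the marginal
log-likelihood; when the variance component is estimated at (near) zero the
log-σ direction is unidentified and the covariance is conditioned on it.
The engine reproduces `lme4::glmer(..., nAGQ = 7)` estimates, standard
errors and σ̂ to ~4 decimals on a common dataset (see
`tests/test_models.py`).  The random-slope sensitivity variant uses a
bivariate Laplace approximation with a profiled penalised-likelihood inner
loop; its fixed-effect SEs are conditional on the variance components, which
is adequate for a sensitivity comparison but not for primary inference.

**Week-window models** regress preterm status on smoke days within each
gestational week 0–35 in separate logistic models.  Each week-w model is
restricted to births whose week w was fully observed before delivery
(GA > 7(w+1) days); late windows therefore condition on surviving past the
window, which is the standard risk-set interpretation.  Weeks with zero
exposure variance are returned flagged, never silently fitted.

**Gestational-age linear model**: mixed linear regression of GA in days on
exposure accumulated from conception to week 32, excluding births before 32
weeks so the exposure window is fixed across the analysis set; fitted by
statsmodels `MixedLM` (Powell fallback when the site variance sits on the
zero boundary).

**Effect modification**: stratified fits plus a pooled fit with exposure ×
modifier product terms; binary modifiers use the Wald z of the product term,
categorical modifiers a multi-df Wald χ² over the interaction block.
Poverty tertiles are computed within the analysis sample.  No
multiple-testing adjustment is applied anywhere; interpretation is expected
to lean on trends across thresholds and durations rather than single
p-values.

**Sensitivity suite**: (1) trimester-specific exposure; (2) adjustment for
pregnancy-average temperature and ambient (non-wildfire) PM2.5; (3) site
fixed effects (with rank-revealing pruning of columns made collinear by the
site dummies); (4) site random intercept + random slope on exposure; (5)
complete-case analysis.

**Spline bases** are deterministic given the data: natural cubic with
interior knots at quantiles and boundary knots at the range, and a low-rank
thin-plate smooth (r² log r kernel on farthest-point knots, reduced to the
requested df by eigendecomposition of the knot kernel).  Both bases are
centred and orthonormalised (span-preserving, since every model carries an
explicit intercept): the raw truncated-power columns are otherwise so badly
scaled — and, for calendar year, so nearly constant — that Newton solvers
fail.  `build_design` caps spline df at the number of distinct values
present so small strata remain estimable; the `spline_basis` primitive
itself enforces the strict df contract.

## Multiple imputation

Chained-equation sweeps run independently within each site (sites under 50
records fall back to a pooled model with a site indicator).  Continuous
variables use Bayesian linear regression with predictive mean matching
(5 donors), binary variables a logistic model with an approximate posterior
coefficient draw, categorical variables a ridge-regularised multinomial fit
on a bootstrap resample with softmax sampling.  Predictors default to the
analysis covariates plus total smoke days and the outcome (the congenial
choice for downstream outcome models).  Defaults m = 10 and 10 sweeps are
configurable; the Monte-Carlo studies use m = 5 with 3 sweeps, which is
ample for a single masked covariate.  Rubin pooling returns the mean
estimate, total variance `within + (1 + 1/m)·between`, and t-based intervals
with the standard small-sample degrees of freedom.

## The synthetic data-generating process

The generator is the package's test bed: it emulates the joint structure the
analysis needs (episodic exposure, clustering, a known hazard) without
claiming to reproduce any real cohort's microdata.

**Daily exposure.**  Each tract follows a two-state (smoke/no-smoke) chain.
The entry probability is `p_enter · region_rate · frailty · season(doy)`
with a cosine season peaking in mid-August (relative amplitude 0.65) and a
mean-1 gamma tract frailty (shape 3.4) producing the strong between-tract
overdispersion of smoke-day counts and the small fraction of pregnancies
with no exposure at all.  Each smoke run draws a shared run-level intensity
effect r ~ N(0, 0.78²); day concentrations are
`exp(0.95 + r + N(0, 0.41²)) · region_intensity` µg/m³, and non-smoke days
are exactly zero.  Persistence is state-dependent:
`logit p_stay = logit(0.46) + 0.55·r + (0.12·r − 0.55)·1[run age ≥ 2]` — more
intense episodes last longer (as large fire events do), and runs face one
extra stopping penalty after their second day, which reproduces the observed
duration grading of wave prevalences.  With the modulation switched off the
chain is the plain two-state Markov chain whose stationary smoke fraction
`p_enter / (p_enter + 1 − p_stay)` the tests verify by simulation.

These parameters were calibrated once, by simulation, so that the default
20,000-pregnancy cohort reproduces published national-cohort marginals
within ±15%: mean daily wildfire PM2.5 0.36 µg/m³, 22.2 smoke days (>0),
12.2 (≥2.5), 6.2 (≥5), 1.8 (≥10), 99.2% of pregnancies with any exposure,
and the 3 × 3 table of wave prevalences from 80.6% (≥2.5 µg/m³, ≥2 days)
down to 6.0% (≥10 µg/m³, ≥4 days).  A single lognormal cannot satisfy all
three smoke-day intensity fractions exactly; the run/day variance split and
the intensity–persistence coupling are what make day counts and wave
prevalences jointly attainable.  Regional rate and intensity multipliers
(Midwest smoke-day-rich, West intensity-rich) reproduce the qualitative
regional pattern.

**Cohort.**  30 sites allocated to the four census regions by birth share
(West 29%, Midwest 17.8%, South 21.4%, Northeast 31.8%), uneven gamma site
weights, 40 tracts per site (≈ 17 births per tract — residences in a
national cohort are dispersed), tract coordinates in rough regional
bounding boxes, and tract poverty from a gamma distribution (mean 14.7%,
SD ≈ 13%).  Covariates are drawn from documented marginals (age
N(30.6, 5.6²) truncated to 14–50, 48.8% female infants, race/ethnicity/
education/parity/BMI/tobacco/alcohol shares as in `COVARIATE_MARGINALS`).
Conception dates are uniform over the window; 10% of pregnancies move once,
uniformly in time, to another tract of the same site.

**Outcomes.**  Weekly Bernoulli trials over gestational weeks 22–36 with
logit hazard = baseline(w) + β_exposure · cumexp(w) + covariate terms + site
intercept (N(0, 0.3²) by default).  The default baseline rises geometrically
to week 31, steps up at 32–33, and plateaus at 34–36, calibrated so the
marginal preterm fraction is ≈ 8.4% split ≈ 1.0% / 0.9% / 6.4% across
< 32, 32–33 and 34–36 weeks.  Default exposure effect: OR 1.02 per
cumulative ≥10 µg/m³ smoke day.  Survivors draw a term gestational age from
a categorical distribution over completed weeks 37–42
(8/22/38/22/8/2%) with a uniform day within the week — a documented
convention, as term GA distributions are not part of the calibration
surface.  Covariate log-ORs (e.g. +0.45 for Black race, +0.13 per SD of
neighbourhood poverty, +0.25 for tobacco) produce descriptive gradients of
realistic size and are recoverable by the model layer.

**What the generator does not emulate**: spatial error in the upstream
exposure model, within-tract heterogeneity, real tract geometry, correlation
between covariates (they are drawn independently), between-year trends in
fire activity, multiple births per individual, and outcome-dependent
missingness (only MCAR/MAR mechanisms are provided).  Passing tests
demonstrate that the estimators are correct under the stated model, not that
any particular real-world association holds.

## Validation design

* **Oracle equivalence**: smoke-day and smoke-wave counters match naive
  brute-force enumeration exactly on 1,000 random vectors.
* **IRLS agreement**: with clustering disabled, pooled-logistic coefficients
  match an independent Newton/IRLS solver to 1e-6 on a 5,000-pregnancy
  cohort.
* **Parameter recovery**: β = log 1.02 per cumulative smoke day; 120
  replicate cohorts of n = 3,000 with 8 sites and σ_site = 0.3 give mean
  relative bias within 10% and 95% CI coverage within [0.91, 0.98].
* **Type-I error**: 200 null replicates of n = 1,500 hold the rejection rate
  of the exposure Wald test and the sex-interaction test within two
  Monte-Carlo SEs of 0.05.
* **Critical-window localisation**: an effect confined to gestational weeks
  18–24 is localised there by the week-window models in a majority of 100
  replicates of n = 2,000.
* **MI consistency**: with 20% MCAR missingness in BMI, the Rubin-pooled
  exposure estimate stays within one pooled SE of the full-data estimate in
  ≥ 90% of 100 replicates of n = 1,200, and pooled variance always dominates
  the mean within-imputation variance.

Monte-Carlo problem sizes are the package's own choices, set so each study
resolves its acceptance band with adequate Monte-Carlo margin while the
whole suite runs in minutes on one CPU.  The simulation studies use flat
weekly baselines (so every gestational week has events at moderate n) and
the unadjusted covariate set where the generator has no covariate effects.
One property is deliberately reformulated: under a null hazard, regressing
preterm status on *total* smoke days is not a null regression, because total
exposure is mechanically shorter for shorter pregnancies — the very artifact
the time-updated person-period design exists to avoid.  The null-linkage
test therefore uses smoke days in the fixed window conception..week 22,
whose p-values are verified uniform.

## Known limitations

* The AGQ engine supports a single scalar random intercept per cluster (plus
  the bivariate Laplace variant for the random-slope sensitivity); crossed
  or nested random effects are out of scope.
* Wald intervals throughout; no profile-likelihood or bootstrap intervals.
* The thin-plate smooth uses at most 40 knots; with strongly clustered
  residences its effective df saturates near the number of distinct
  locations, and `build_design` caps df accordingly.
* Imputation's posterior draws are approximate (normal approximation /
  bootstrap); strict properness matters little at the m and missingness
  rates exercised here but would for heavy MNAR-adjacent use, which is not
  supported.
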