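# Methods

## The model chain

### Flight curves and indices

For one transect, species and year, let `y_i` be the count on day-of-year
`d_i` divided by the transect length in km. The within-season expectation
is modelled as a smooth `E[y] = exp(f(d))` with `Var[y] = phi * E[y]`
(quasi-Poisson): counts are overdispersed relative to Poisson but the mean
curve is all the indices need. `f` is a penalized cubic B-spline with basis
dimension 4 — effectively a gently penalized cubic on the season's span —
fitted by penalized IRLS (statsmodels `GLMGam`). The smoothing parameter is
chosen by generalized cross-validation with the Pearson statistic,
`GCV(alpha) = n * X2 / (n - edf)^2`, the appropriate score when only the
first two moments are assumed; the search is over 21 log-spaced penalty
weights in [1e-4, 1e6], which brackets everything from an unpenalized cubic
to a constant. Dispersion is reported as Pearson X2 / (n − edf).

Two zero pseudo-counts are appended, 7 days before the first walk and 14
days after the last. One zero per boundary is the minimal reading of
"zeros added before/after the season" and, with a log link, is enough to
force the smooth toward zero outside the observed window; with a 4-function
basis additional boundary zeros change almost nothing (edge behaviour
only).

The fitted curve is evaluated on a grid of 0.01-day steps between the two
pad days. Then

* `PAI = sum(density) * 0.01` (rectangle rule — the grid is so fine that
  the difference from adaptive quadrature is < 0.05%),
* `Onset = ` the smallest grid day where the cumulative rectangle area
  reaches 20% of the total (first crossing, no interpolation: the grid is
  finer than any reportable precision),
* `Duration = ` the 80% day minus the 20% day.

**Minimum-data rule.** A season is fitted only if it has ≥ 5 points
(including the pads) and ≥ 3 non-zero counts; otherwise the season-index
row carries `usable = False` and the event is logged. Monitoring data give
no principled universal rule here; this one rejects exactly the seasons
where a 4-parameter smooth would be chasing one or two observations.
Non-convergent fits (possible under pathological inputs) are likewise
flagged and excluded, never silently interpolated.

### Seasonal climate predictors

Monthly station values are aggregated per *flight year* y: autumn = Sep–Oct
of y−1 (pre-hibernation larval feeding), winter = Nov y−1 – Apr y
(overwintering), spring = May–Jun y (post-hibernation feeding), summer =
Jul–Aug y (adult flight). Temperatures (mean, max, min, ground-min) are
averaged over the season's months; precipitation and snow days are summed.
The 21 predictors are `P_tot_*`, `T_avg_*`, `T_max_*`, `T_min_*`,
`T_ground_*` for the four seasons plus `Snow_days` (winter). Any missing
source month leaves the aggregate missing; missing predictors are skipped
(and logged) at the screening stage, never imputed.

### Screening

One analysis dataset = one species × transect group × year range, joined
with its station's seasonal predictors. Responses are log PAI, log Onset
and log Duration. The null model is `response ~ Transect` (treatment-coded
fixed factor); each predictor is standardized to zero mean and unit sample
(n−1) variance *within the dataset* and added alone. Models are Gaussian
GLMs, i.e. OLS, with

    AIC = n log(2 pi RSS/n) + n + 2 (p + 1),

the maximum-likelihood convention counting the variance as a parameter
(matching R's `AIC` for `lm`; only within-dataset differences matter — the
convention constant cancels in every ΔAIC). Classes: ΔAIC < −6 strong,
< −2 moderate, else none. No multiple-testing correction is applied: the
screening is explicitly information-theoretic, every ΔAIC is reported, and
nothing is hidden behind a significance filter.

Additional analyses per dataset:

* **Trend**: `response ~ Transect` vs `+ Year` (year unstandardized, slope
  per calendar year).
* **Biennial contrast**: `log PAI ~ Transect + Year` vs `+ Parity`
  (odd/even year); `exp(coefficient)` is the odd/even abundance ratio.
* **AR(1) check**: the transect-factor null refitted by maximum likelihood
  with within-transect AR(1) errors across years (gaps bridged as
  `phi^gap`), against iid errors. Implemented directly (whitening
  transform + profile likelihood over phi on (−0.99, 0.99)); ML rather
  than REML so the two AICs are comparable. `use_ar1` is simply which AIC
  is smaller.
* **Abundance vs phenology**: the four-model set (null, + log Onset,
  + log Duration, + both), ΔAIC against the best.
* **Onset–Duration correlation**: Pearson r with the Fisher-z interval
  `tanh(atanh(r) ± 1.96/sqrt(n−3))`; |r| = 1 collapses the interval and is
  flagged degenerate.

## The synthetic-data generator

The generator emulates the study design the pipeline targets, with every
ground-truth quantity retained for recovery testing.

* **Design**: 3 transects × 12 years by default (36 transect-years, the
  scale of a long single-mountain dataset; the pipeline-scale checks use
  4 × 15). Walks: for each week of the 1 July – 15 August window (days
  182–227), 2–4 walks on distinct random days — the irregular,
  weather-limited effort of real schemes.
* **Abundance**: `log A_ty = baseline_t + sum_c slope_c z_c(y) +
  parity(y) * biennial_log_ratio/2 + N(0, 0.5)`. The year-process SD of
  0.5 reproduces the per-SD slope standard errors (~0.09–0.10) that
  screening tables at n ≈ 36 typically show, so planted-effect power in
  tests reflects realistic conditions.
* **Phenology**: peak day `mu_ty = 203 + sum_c phen_slope_c z_c(y) +
  N(0, 3)` days, drawn independently per transect-year.
* **Counts**: negative-binomial with mean `L * A * f(t)` and size
  theta = 5 (variance/mean ≈ 2–3 at typical daily means — the
  overdispersion quasi-Poisson fitting assumes; Poisson is the
  theta → inf limit). `f` is the unit-area Gaussian density with
  within-season SD 8 days (a 20–80% duration of ~13.5 days); a two-piece
  Gaussian (unequal left/right SDs, closed-form quantiles) is available to
  probe skewed emergence.
* **Climate**: a seasonal-sine monthly climatology of a ~1300 m
  central-European station (July mean 11 °C, January −7 °C, 100 mm/month,
  winter snow). Year-to-year variation enters as one anomaly per
  flight-year season: a temperature shift (SD 1 °C) shared by all four
  temperature variables — which is what keeps `t_min ≤ t_avg ≤ t_max`
  intact and also reproduces the strong within-season correlation of
  temperature variables seen in real stations — a mean-one lognormal
  precipitation factor (log-SD 0.2), and a snow-day shift (SD 8
  days/month), plus small independent monthly jitter. Effects are planted
  against the *realized* z-scores of the seasonal aggregates, so recovery
  tests are exact rather than attenuated.

What the generator deliberately does **not** emulate: detection
probability and observer differences, within-day weather effects on
counts, correlated phenology across transects, multi-year (cohort-level)
biennial development, spatial climate gradients within a transect group,
and long-term climate trends. Passing recovery tests therefore shows the
*estimators* are correct and calibrated under the stated stochastic model;
it does not validate those field-level complications.

## Numerical choices and degenerate inputs

* Penalty search: discrete GCV minimum over the 21-point log-grid; ties
  break toward the first (smallest) penalty. A finer search changes the
  indices by far less than sampling noise.
* Quantile extraction: first grid crossing; monotone in q by construction.
* Standardization refuses constant vectors (zero variance) — the ledger
  logs and skips such predictors.
* OLS designs are rank-checked; rank deficiency is an error, not a silent
  pseudo-inverse fit.
* `pai = 0` (all-zero density) makes quantiles undefined — an error, and
  such seasons are unusable upstream anyway.
* AR(1) likelihood at the phi bounds is finite (|phi| ≤ 0.99); the
  profile optimum is found by bounded scalar minimization.
* Simulated precipitation factors are mean-one lognormal, so configured
  monthly means are exact expectations, not medians.

## Problem sizes used in the checks

Scenario checks run at the design scale they test: n = 36 (3 × 12) for
null calibration and climate-effect recovery, n = 40 (4 × 10) for the
biennial contrast, 3 × 12 for the AR(1) rates (200 replicates each), 100
replicate pairs for the phenology-shift check, and 4 transects × 15 years
(60 curve fits) for the end-to-end determinism run. These match the
transect-year counts of the monitoring datasets this pipeline is designed
for, where degrees of freedom — not replication — are the binding
constraint.

## Known limitations

* The k = 4 smooth cannot represent multimodal flight curves (partial
  generations, strongly split emergences); for univoltine mountain species
  this is the intended behaviour, not a bug.
* PAI is a *relative* index: it scales with detectability and is
  comparable across years within a transect, not across species or
  schemes.
* The screening fits predictors one at a time by design; it ranks
  individual evidence and cannot separate correlated climate variables.
* With ~10–15 years per dataset, the AR(1) check has modest power; an
  "iid preferred" outcome is evidence of absence only in the ΔAIC sense.
* The Gaussian GLM treats log-indices as homoscedastic across transects;
  strong transect-level variance differences would call for weighting the
  model does not implement.
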