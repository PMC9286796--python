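# Methods

`spreadwait` estimates how long an invading insect population waits between
first detection and local establishment, quadrat by quadrat, from
pheromone-trap count data, and then asks which environmental and
anthropogenic drivers shorten or lengthen that wait.  This note documents
the statistical machinery, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## 1. From trap records to quadrat series

Trap-year records (projected x/y in meters, year, integer moth count) are
aggregated to a 5 × 5 km quadrat grid.  Before gridding, any trap-year
record strictly within 1.5 km of a treatment footprint active in that year
is removed — 1.5 km exceeds both treatment drift and the moths' natural
dispersal, so surviving records reflect untreated dynamics.  Treatment
footprints are discs (center, radius); distance to the footprint is
distance to the center minus the radius.

Conventions, arbitrary but fixed:

* grid cells are half-open `[edge, edge + size)` in both axes — a point on
  a shared edge belongs to the higher-index cell;
* the buffer is strict (`< 1500 m` drops, `= 1500 m` keeps);
* the yearly quadrat statistic is the **median** count over traps (even
  counts: mean of the two middle order statistics); the median is
  insensitive to trap-number variation and to the heavy upper tail of
  catch distributions;
* years in which no trap reported are missing, not zero.

Two filters restrict the analysis to quadrats that plausibly turned from
uninvaded to established during monitoring, applied in this order:

1. **Low catch** — total raw catch over all traps and years below 10
   moths: clearly never established.  ("Raw total" rather than a sum of
   medians, because the count of moths caught is a property of traps, not
   of the median series; a config switch provides the median-sum variant.)
2. **Pre-established** — the first non-missing yearly median is already
   positive: likely established before monitoring began.  Years without
   traps carry no record, so leading missing years are skipped, not
   treated as zeros.

## 2. The establishment model

Each quadrat's yearly median series `y_t` is modelled, on the transformed
scale `z_t = log(1 + y_t)`, as a Gaussian local-level (random-walk trend)
state-space model:

    z_t      = mu_t + eps_t,      eps_t ~ N(0, sigma2_eps)
    mu_{t+1} = mu_t + eta_t,      eta_t ~ N(0, sigma2_eta)

The log1p transform keeps the Gaussian observation model consistent with
nonnegative, right-skewed counts; a Gaussian on the raw counts would place
probability below zero and make "probability of a zero-moth median"
ill-defined.  An identity transform is available for sensitivity checks.

**Fitting.** A Gibbs sampler alternates (a) a forward-filter
backward-sample (FFBS) draw of the full level path given the variances —
an exact joint draw via the Kalman filter — and (b) conjugate
inverse-gamma draws of `sigma2_eps` and `sigma2_eta` given the path.
Missing years skip the measurement update; the time index still advances
(missing-at-random).  Defaults: 2,000 iterations, 500 burn-in (the
per-quadrat pipeline scan uses 1,200/200 — thousands of short fits).  All
draws for one fit come from a dedicated stream keyed by (seed, row, col,
target year), so any single fit can be reproduced in isolation and the
whole pipeline is deterministic given the seed.

**Priors.** Inverse-gamma, shape 1, scale `0.5 * Var(diff z)` for the
observation variance and `0.05 * Var(diff z)` for the level-innovation
variance, floored at 0.01 to stay proper on degenerate (constant or
all-zero) series.  Two deliberate choices here: the scales key off the
*differenced* series — `Var(diff z) = 2*sigma2_eps + sigma2_eta`
regardless of how far the level wanders, whereas the marginal variance is
inflated by level variation and was found in calibration studies to bias
both variance posteriors upward — and shape 1 rather than a more
informative shape, because shape-2 priors left the 95% credible intervals
covering simulated true variances in only ~85–89 of 100 replicates, while
shape 1 yields 93–99 across the regimes examined (the package's
calibration study in `tests/test_acceptance.py` re-runs one such regime).

**Forecasting and the probability of zero.**  For target year `t` the
model is refit on the expanding window from the start of monitoring
through `t − 1` (a fresh fit per target year, not in-sample smoothing),
requiring at least 10 observed years — with a 1985 start the first target
year is 1995.  Each retained draw is propagated one step with a fresh
level innovation, observation noise is added, and the transform inverted
(`y* = max(exp(z*) − 1, 0)`).  The probability that year `t`'s median is
zero is

    p_t = P(y*_t < 0.5),

a median that rounds to zero.  An alternative latent criterion
`P(mu_{t} < log 2)`, ignoring observation noise, sits behind a config
switch.

**Establishment and waiting time.**  Detection year `D` is the first year
with a median of at least one moth.  The establishment year `E` is the
earliest target year `t ≥ D` with `p_t < 0.01` (strict inequality; 0.01
is deliberately conservative — establishment is declared only when the
model is more than 99% sure moths will be trapped).  The waiting time is
`W = E − D`.  Quadrats that never reach the threshold are excluded as
never-established.

**Left-censoring.**  If the very first computable probability is already
below 0.01, or detection precedes the first computable year and
establishment is declared at its immediate start, the transition was
never actually observed: establishment may lie anywhere in the unexamined
gap, and `E` is only an upper bound.  Such records carry a
`left_censored` flag; they remain in the analysis table (their waiting
time is still the value the method produces) but are excluded from
ground-truth recovery statistics, where a censor bound would be scored as
if it were a point estimate.

**Validation.**  One-step predictive means are pooled against observed
medians across quadrat-years and summarized by their Pearson correlation,
with a permutation null available in the tests.

## 3. The regression stage

For each included quadrat the design collects: the ten driver means
(winter temperature, maximum spring temperature, summer precipitation,
elevation, host basal area, human population density, wood-heating
housing units, highway density, anthropogenic and natural fragmentation)
as quadrat means of the supplied grids (climate layers averaged 1995–2015
first); two background variables — year of first detection, and the mean
waiting time of the surrounding 3 × 3 neighborhood (focal quadrat
excluded, missing neighbors ignored; an inclusive variant is a config
switch); and nested eco-region labels.  The background variables absorb
the large-scale spatiotemporal structure of the spread and neighborhood
propagule pressure, so the drivers compete only to explain local
departures.

The model is a random-intercept linear mixed model,

    W_i = beta_0 + x_i' beta + alpha_{g(i)} + e_i,
    alpha_g ~ N(0, sigma2_alpha),   e_i ~ N(0, sigma2_eps),

grouped by level-IV eco-region, fit by maximum likelihood (not REML, so
AIC is comparable across fixed-effect structures).  Predictors are
z-standardized within each model's fitting subset, making coefficients
comparable across terms; AIC ordering is invariant to this affine
reparameterization.  All `2^k` driver subsets are enumerated, each
carrying the two background terms and the random intercept; the lowest
AIC wins, ties broken by fewer parameters then lexicographic term order.
`AIC = −2 logL + 2 (k_fixed + 2)`, counting both variance components.  A
subset whose fit fails or returns a non-finite likelihood is logged and
skipped, never silently dropped.  When the random-intercept variance
estimate hits its zero boundary the profiled mixed-model likelihood
degenerates; the boundary ML solution is plain OLS and is evaluated
directly in that case.

Model quality: variance inflation factors `VIF_j = 1/(1 − R²_j)` on the
selected design, and the mixed-model R² pair

    R²_marginal    = s²_f / (s²_f + s²_alpha + s²_eps)
    R²_conditional = (s²_f + s²_alpha) / (s²_f + s²_alpha + s²_eps)

with `s²_f` the variance of the fixed-effects linear predictor over the
fitted rows.  A driver-only marginal R² replaces the numerator by the
variance of the linear predictor restricted to driver terms, using the
full-fit coefficients.  This is a semi-partial *approximation*: exact
when drivers and background variables are orthogonal, and able to exceed
the marginal R² (even 1) under strong driver–background correlation
(suppression); it is reported as computed, not clipped.

## 4. The synthetic invasion generator

The generator produces data with exactly the structure the analysis
assumes, plus full ground truth, so every stage can be checked against a
known answer.

* **Landscape** — one spatially autocorrelated Gaussian field per driver
  (white noise smoothed with a Gaussian kernel, re-standardized to the
  stated marginal mean/sd, so moments are exact at any correlation
  length), and a nested eco-region hierarchy: level-II subregions as
  horizontal bands, level-IV units as square blocks within them.
* **Invasion** — a kinematic wave: arrival year = distance from origin /
  speed, rounded.  The establishment lag is `max(0, round(mu_lag +
  sum_j beta_j x_j + alpha_level4 + noise))` — additive by construction,
  because the regression stage assumes additive effects; this makes
  recovery tests well-posed.  Defaults: mean lag 8 yr; beta = −2 (winter
  temperature), +1 (spring maximum), +0.8 (summer precipitation), +0.5
  (elevation), +0.6 (anthropogenic fragmentation) yr per sd, the other
  five drivers true nulls; random-intercept sd 1 yr; residual sd 1.5 yr.
  Effect sizes are chosen for statistical power in recovery studies, not
  calibrated to any real system.
* **Abundance** — zero before arrival; a low plateau (default 0.7 mean
  moths per trap) from arrival until establishment; then logistic growth
  to carrying capacity (default 300) at rate 2.5/yr, with the logistic
  **midpoint at the establishment year**.  Two semantics are embedded
  here.  First, the waiting-phase population must sit below the density
  of reliable trapping — if the plateau were steadily detectable (median
  ≥ 1 every year), the quadrat would be established by the method's own
  operational definition and the waiting period would not be expressed in
  the data at all.  Second, "establishment year" labels a population
  already past extinction risk (half of carrying capacity), so the growth
  ramp precedes it; centering the logistic at the start of growth instead
  would systematically delay every declared establishment by the time the
  counts take to become unambiguous.
* **Trapping** — cells reached in the first half of the study period
  count as "behind the front" and get the sparse trap density (default 1
  per cell, ~5 km spacing), the rest the dense density (default 3 per
  cell, ~2–3 km spacing), echoing the monitored network's layout at
  reduced density.  Counts are negative-binomial, mean `k · N(cell,
  year)` and size 5 (overdispersed, as trap catches are), with `k` the
  detection scale.  Treatment discs are drawn yearly within an area
  budget (default 1%, at most 2%); they exercise the exclusion geometry
  only — counts are not suppressed.
* **Determinism** — all randomness flows from one seed through
  `SeedSequence` children keyed per stage, so stages can be regenerated
  independently and the full generator is byte-reproducible.

What the generator does **not** emulate: demographic stochasticity and
Allee effects, outbreak cycles, ballooning dispersal kernels, anisotropic
spread, trap relocation across years, spatially clustered treatment
programs, or any calibration to real vital rates.  Passing recovery tests
therefore demonstrate that the estimator chain is correct *under its own
assumptions* — additive lags, a clean wave, stationary trapping — not
that those assumptions hold for any real invasion.

## 5. Validation studies and problem sizes

The studies in `tests/test_acceptance.py` and `scripts/acceptance.py` are
sized to run on one CPU in minutes:

* **Sampler vs smoother** — in known-variance mode the FFBS draws are
  i.i.d. from the exact smoothing posterior; on 20 simulated series
  (T = 30) the per-time-point posterior means are compared to the exact
  Kalman smoother via Monte-Carlo z-scores.  Since 600 honest z-scores
  will exceed 3 about 1.6 times by chance, the check is family-wise
  calibrated: ≥ 98% within 3 SEs and max |z| < 4.5.
* **Variance calibration** — 95% credible intervals for both variances
  against simulated truth, 100 replicates, T = 60, truth
  (sigma2_eps, sigma2_eta) = (1, 0.3); coverage required in [90, 99].
* **Waiting-time recovery** — a 20 × 20 high-detection scenario (6/3
  traps per cell, negative-binomial size 20, plateau 0.85 so detection
  promptly follows arrival, wave speed 10 km/yr so establishment falls
  inside the observation window rather than being right-censored);
  requires Pearson r ≥ 0.8 and mean |error| ≤ 2 yr against truth,
  censored records excluded.  Typical values across seeds: r ≈ 0.84–0.94,
  mean |error| ≈ 1.0–1.3 yr.
* **Filter exactness** — status counts equal a brute-force pure-Python
  oracle, exactly.
* **Sign recovery** — driver-only mixed regressions on true waiting
  times, 50 replicates of ~1,000 quadrats; every |beta| ≥ 0.5 yr/sd
  driver must keep its sign in ≥ 90% of replicates.
* **Selection consistency** — all-subsets AIC with four candidates and
  one true driver (beta = 1 yr/sd, n ≈ 2,000), 100 replicates; 2^4 models
  enumerated each time, true driver selected in ≥ 95%.
* **Determinism** — identical config + seed reproduces byte-identical
  establishment and regression tables.

## 6. Known limitations

* The local-level model is the only structural form offered — no
  seasonal or regression components, and no spatial pooling between
  quadrats during fitting.
* "Probability of zero" depends on the chosen transform and threshold;
  both are config-exposed, and the latent-level alternative can disagree
  near the establishment boundary.
* Establishment declared at the first sub-threshold year lags true
  establishment by roughly the time high counts need to enter the
  one-step history (about +1 yr under the recovery scenario), while
  detection delay works in the opposite direction; the two roughly cancel
  on average but both add noise.
* Left-censoring at the first evaluable year is flagged, not modelled; a
  survival-analysis treatment of censored waiting times is out of scope.
* The driver-only R² estimator is the restricted-linear-predictor share
  described above, with its documented suppression failure mode.
* Inputs must already be in a shared planar meter CRS; no re-projection
  is performed.
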