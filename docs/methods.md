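# Methods

This note records the statistical models, the generative assumptions
behind the synthetic cohorts, the numerical choices, and the limits of
what the test suite demonstrates.

## Trajectory model and estimation

Each phenotype is modeled per mouse as a linear trend in age with
Gaussian random intercepts and slopes:

y_ij = β0 + β1·male_i + β2·treat_i + β3·t_ij + β4·treat_i·t_ij
+ b0_i + b3_i·t_ij + ε_ij,

with t_ij = (age_ij − 578 d)/100. Centering age at the 19-month
enrollment baseline (578 d with the fixed conversion 1 month = 30.44 d;
24 mo = 730 d, 36 mo = 1095 d) affects only the intercept; dividing by
100 puts all slopes on the per-100-days reporting scale, a pure
reparameterization (checked to machine precision in the tests).

Fitting is REML via statsmodels `MixedLM` with the lbfgs optimizer.
Non-convergence triggers a fallback ladder — free intercept/slope
covariance → independent random effects → random intercept only — with
each step recorded on the returned fit. If the data lie exactly on the
fixed-effect plane (a zero-noise simulation), REML is singular and the
exact OLS solution is returned with zero variance components.

Wald tests use a t reference with residual degrees of freedom
(n_obs − n_fixed); the fit's `df_method` field says so. Small-sample
df corrections (Kenward–Roger, Satterthwaite) are not implemented: no
installed Python mixed-model stack provides them, and at the cohort
sizes this package targets (hundreds of observations) the residual-df t
and the corrected tests differ negligibly for the slope contrasts. One
test cross-checks the REML fixed effects against an independent lme4 fit
through Rscript and they agree to ~1e-4.

Mice contribute only if they have ≥2 observations of the phenotype
(repeated measures need two scans); after a fracture, the fracture-visit
scan and all later scans for that animal are removed, and animals left
with fewer than two scans are dropped entirely.

Treatment fits pool the treated arm with the controls in one model
(β2/β4 contrasts) rather than fitting arms separately — that is what the
model equation implies, and it shares the residual variance estimate.

Rates are reported three ways: per 100 days (β3), per year (×365/100),
and — for interventions — as the sparing percentage
100·β4/|β3_control|, the fraction of the age-related change the
treatment prevents per unit time (100% = change fully arrested; negative
values mean acceleration).

### Multiplicity

Across a table of phenotypes, q-values follow the Storey procedure: the
null proportion π0 is estimated from the tail counts
π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05, …, 0.95, smoothed with a cubic
spline and read off at λ = 0.95, clipped to (0, 1]; then
q_(i) = π0 · min_{j≥i} m·p_(j)/j. With π0 fixed at 1 this is exactly
Benjamini–Hochberg (asserted against the statsmodels implementation).
With fewer than 32 p-values π0 is not estimated (set to 1): the tail
counts are too noisy for the spline to be meaningful.

## Synthetic cohorts

The generator mirrors the structure the estimators assume; its defaults
are the study conditions the package is built around:

- **Design**: 20 mice per sex per arm enrolled at 578 d, visits every
  91 d (quarterly) until death or 1095 d. Visits sit on a shared grid;
  an optional ±7 d uniform jitter flag exists but is off by default (the
  exact grid makes closed-form checks sharp and matches synchronized
  surveillance).
- **Mortality**: Gompertz hazard a·e^{bt} with a = 7.5e-6/d,
  b = 0.008/d, giving a median lifespan near 27 months for an animal
  alive at 19 months and ~99% mortality by 36 months — plausible for
  aged C57BL/6J; these are modeling choices, not published estimates.
  Sex and treatment act proportionally on the hazard. Death ages are
  drawn by inverting the conditional survivor function given survival to
  enrollment.
- **Rolling recruitment**: a death before the follow-up cap enrolls a
  replacement at the next grid visit after the death, provided at least
  two visits remain (a replacement that could only be scanned once would
  be excluded from analysis anyway). Replacements are themselves subject
  to mortality and replacement.
- **Traits**: per-mouse (b0, b3) are bivariate Gaussian (default
  correlation 0 — nothing in the target studies pins it down; it is a
  spec field and the estimator recovers it when nonzero), residuals iid
  Gaussian. Where recovery studies need "plausible" variance components
  the package uses, e.g. for a percent-bone-volume-like trait,
  sd_intercept 3.0, sd_slope 0.5/100 d, sd_residual 1.5 (implying a
  fixed-slope SE ≈ 0.08–0.11 at N = 89 with 4–5 quarterly visits, the
  right order for such cohorts); for glucose 15/3/10 mg/dl; for body
  mass 4/0.3/1 g; for tortuosity 0.02/0.003/0.01. These are labeled
  plausible, not study-derived: the studies publish slopes, not variance
  components.
- **Fractures**: a constant hazard that switches on at 730 d (24 mo);
  at the default 2e-4/d roughly 2–4% of animals alive past 24 months
  fracture before 36 months. First event only; observations from the
  fracture visit onward are censored by the analysis layer.
- **Spines**: each mouse-visit's true tortuosity comes from the trait
  model; the emitted centerline is a circular arc at a random rigid pose
  whose half-angle is solved (Brent) so that the *polyline* tortuosity
  of the sampled points equals the target to ~1e-12 — the scorer
  round-trips the generator by construction, so end-to-end slope
  recovery tests the measurement chain, not interpolation error.

A single `numpy.random.Generator` drives everything; fixed seed ⇒
byte-identical outputs (asserted).

What the generator does not emulate: floor/ceiling effects and skewed
residuals in real phenotypes, measurement drift between scan sessions,
informative dropout (death correlated with trait level), per-mouse visit
jitter by default, and litter/cage clustering. Passing recovery tests
therefore demonstrates estimator correctness under the stated model, not
robustness to these real-data features.

## Tortuosity geometry

Tortuosity = 1 − chord/arc on the ordered centerline, arc length being
the sum of segment lengths (no spline smoothing; the quantity is defined
by landmark distances). It is invariant under rigid motion and uniform
scaling (asserted to 1e-12) and zero iff the points are collinear.
Resampling is linear and uniform in arc length, preserving endpoints;
on smooth curves the resampled score converges to the analytic value as
the step shrinks (semicircle at step r/100 is within 1e-3 of 1 − 2/π).
The landmark span is C1→L2, taken from the defining formula; landmark
identification itself is out of scope — landmarks arrive as the first
and last points of the centerline. The femoral analysis window is the
2 mm centered on the diaphysis midpoint; a femur shorter than the window
is an error, never a clipped window. Scan-log QC compares a configurable
key set against a reference log, numbers at relative tolerance 1e-6,
everything else by exact string match; missing keys are their own
deviation kind.

## Cross-sectional comparisons

Young-vs-aged group means use Welch's unequal-variance t-test (the
pooled test is available by flag; with genetically identical mice the
variances still differ by age, which is the point of the variance
analysis, so Welch is the safer default). Sex adjustment, when
requested, comes from a linear model with a sex covariate. Variance
change is tested with Brown–Forsythe (median-centered Levene), chosen
for robustness to non-normality; the variance ratio old/young is
reported alongside. Fracture incidence is k fractured among n distinct
animals scanned at ≥ the minimum age (24 mo), as a percentage rounded to
one decimal.

## Survival

Cox partial likelihood with Efron tie handling (death days in rodent
studies are heavily tied once rounded). The default time axis is
time-on-study from enrollment; age-as-time with left truncation at the
entry age is a flag. One model per treatment arm versus controls, sex as
a covariate (or strata). The proportional-hazards check fits the
literal treatment × follow-up-time interaction: follow-up is split into
episodes at the observed event times and a time-varying covariate
treat·t is added (lifelines `CoxTimeVaryingFitter`); the returned
p-value is uniform under proportional hazards (calibration asserted) and
sensitive to an HR that reverses mid-study.

Recovery studies summarize replicate hazard ratios by the geometric mean
(exp of the mean log-HR): log-HR estimates are symmetric about the
truth, while arithmetically averaging ratios is upward-biased by
Jensen's inequality (~+2% at 60 animals/arm), which would contaminate a
bias check. The Monte-Carlo SE is mapped to the ratio scale by the
delta method.

## Power engine

A mouse observed at times t_1..t_k has OLS-slope variance
V = σ_slope² + σ_resid²/S_xx; the two-group normal-approximation sample
size is N = 2(z_{1−α/2}+z_{power})²·V/d² per group with
d = |β3|·effect/100, ceiling, minimum 2. Attrition (independent
per-interval dropout with monotone loss to follow-up) inflates N by the
reciprocal of expected schedule completeness. z-quantiles are the
default; a t-correction flag iterates with df = 2N − 2 and changes N by
at most one animal in the ranges of interest.

The formula is never trusted on its own: `monte_carlo_power` simulates
two-arm cohorts from the generative model and tests the slope contrast
per replicate. The default test is Welch's t on per-mouse OLS slopes —
on the balanced common-grid designs the oracle simulates, the per-mouse
slope is the sufficient summary for the slope contrast, and the
vectorized simulation makes a 3×3 grid at 1000 replicates/cell run in
well under a minute. A `method="lmm"` path refits the full mixed model
per replicate; a test checks the two paths agree within binomial noise.
Across the default grid the closed-form N achieves simulated power
within ±0.02 of the 0.80 target, and N−2 per group does not comfortably
clear it.

Power tables enforce their monotonicity invariants (N nonincreasing in
effect size and visit count) rather than assuming them.

## Problem sizes in the recovery studies

The acceptance script and study-scale tests use: 89 mice (50 M / 39 F,
4 quarterly visits, 200 replicates) for the bone-volume slope; 65 mice
(6 quarterly visits, 200 replicates) for blood glucose; 217 mice
(110 M / 107 F, biweekly visits to 36 months under the default Gompertz
mortality, 100 replicates) for body mass; 60 animals per arm and 500
replicates for the survival hazard ratio; and 60 mice × 4 visits × 200
replicates for the tortuosity chain (each observation is a constructed
centerline scored geometrically before model fitting). These sizes give
Monte-Carlo standard errors comfortably below the effects being
recovered while keeping a full run to a few minutes.

## Known limitations

- No small-sample df correction (see above); p-values for tiny pilot
  datasets (a handful of mice) should be treated as approximate.
- The q-value π0 spline needs a few dozen p-values; below that the
  procedure intentionally degrades to Benjamini–Hochberg.
- The power engine addresses two-arm slope-difference designs on a
  common visit grid; cross-sectional (single-visit) power and >2-arm
  designs are out of scope.
- `check_proportional_hazards` grows the episode-split data quadratically
  with events; for cohorts beyond a few thousand animals the Schoenfeld
  residual test would be the pragmatic substitute.
- The pipeline's treatment-effect tables fit one phenotype × arm at a
  time; cross-phenotype covariance is not modeled.
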