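# Methods

## The model

`previnc` estimates age-specific incidence of a chronic, irreversible
condition from two age-stratified prevalence surveys taken several years
apart. The underlying model is the illness-death model: three states
(Healthy, Diseased, Dead) with transitions governed by the incidence
`i(t, a)`, the mortality of the non-diseased `m0(t, a)` and of the diseased
`m1(t, a)`. Writing `p(t, a)` for prevalence, `m = (1-p) m0 + p m1` for
general mortality and `R = m1/m0` for the mortality rate ratio, prevalence
satisfies the transport PDE

    (∂t + ∂a) p = (1 - p) [ i - m p (R - 1) / (1 + p (R - 1)) ].

For conditions and age ranges where mortality is negligible or
non-differential (`R = 1`) — diabetes in youth being the motivating case —
the mortality term vanishes identically and

    (∂t + ∂a) p = (1 - p) i.

Along a characteristic (a birth cohort, `a - t` constant) this is an ODE in
one variable, and with `q = -log(1 - p)` (the cumulative hazard) it reads
`dq/dτ = i`: the log-survival of the healthy state accumulates incidence
linearly. All estimation in this package rests on that identity.

## Forward solver

`solve_forward` integrates the characteristic ODE with classical RK4.
Ages live on single-year intervals `[a, a+1)`, a = 0..19; prevalence curves
are indexed by age attained at the survey date. Rates are read once per
sub-step (default 0.1 y) at the sub-step age midpoint, so a step never
straddles an age-interval boundary: piecewise-constant rate tables are
integrated exactly interval by interval, and the scheme's observed
convergence is 4th order (error falls ~16x per step halving). Cohorts
crossing age 20 before the target year leave the surveillance window and are
dropped; cohorts born after the start enter at age 0 with a configurable
birth prevalence (default 0 — congenital disease is taken as negligible).
Solutions are checked to remain in `[0, 1)`; leaving it beyond 1e-9 raises a
`NumericalError` naming the characteristic.

## Inversion: incidence from two cross-sections

Assume incidence constant in calendar time over the inter-survey gap
(`g` years, integer — this operationalizes "average incidence over the
period") and piecewise-constant in single-year age intervals. Integrating
`dq/dτ = i` along the cohort observed at age `a1` in the second survey
gives one exact linear constraint per cohort:

    Σ_{k = max(0, a1-g)}^{a1-1} i(k) = log[(1 - p0(a1-g)) / (1 - p1(a1))],

with `p0 ≡ 0` for cohorts born between the surveys. For g = 8 this is 19
constraints in 19 identifiable unknowns (the interval `[19, 20)` appears in
no constraint); the system is exactly determined and noise-free input is
inverted exactly.

On real survey data the exactly-determined solve is an ill-conditioned
deconvolution: single-year estimates carry standard errors comparable to or
larger than the rates themselves, and the nonnegativity constraint then
rectifies that noise into systematic upward bias of any weighted average of
the estimates. The default estimator therefore:

1. **whitens** the constraints by the delta-method binomial standard
   deviation of each right-hand side, `var(q̂) ≈ p/((1-p) n)` with a
   continuity floor `(cases + 0.5)/(n + 1)` so empty cells get a finite
   noise scale (requires the survey denominators; without them the plain
   exact solve is used);
2. adds a **third-difference roughness penalty** `w ‖D₃ i‖²` whose null
   space (quadratic age profiles) preserves both peaked and
   monotone-rising incidence shapes under heavy smoothing;
3. selects `w` by **restricted maximum likelihood** on the whitened system
   — the standard empirical-Bayes smoothing-parameter choice of penalized-
   spline GAMs — maximized over a 33-point log grid from 1 to 1e16, made
   O(grid x n) per call by a one-off Cholesky + eigendecomposition;
4. solves the penalized system by **nonnegative least squares**
   (`scipy.optimize.nnls`), so reported rates are nonnegative by
   construction;
5. fills unidentified intervals (age 19 for g = 8) by **linear
   extrapolation** from the last two identified intervals, floored at 0 and
   flagged `identified = False`. Extrapolation tracks both rising and
   falling boundary shapes, where carrying the last value forward
   systematically overshoots declining and undershoots rising profiles.

Because the data term scales with the denominators while the prior does
not, the selected smoothing vanishes as noise → 0: noise-free input is
still recovered to solver tolerance. Constraints with negative right-hand
sides (prevalence falling along a cohort — impossible under the model
without excess mortality, but inevitable under sampling noise) are floored
at zero with a warning.

A second estimator, `estimate_incidence_finite_difference`, reads the
simplified PDE as a directional derivative: `i(ā) ≈ [p1(a1) - p0(a0)] /
(g (1 - p̄))` at the cohort mid-age. It averages incidence over the whole
gap, so on curved profiles it deviates from the exact inversion by the
Jensen gap of the window (≈ g²/24 x relative curvature; ~13% at a Gaussian
peak of width 4.5 y). It is kept as an independent cross-check; the
pipeline warns when the median disagreement across identified ages exceeds
10%.

## Uncertainty

Percentile bootstrap, parametric on the sampling model of the surveys: per
replicate, case counts are redrawn `Binomial(denominator, p̂)` in every
(stratum, age, survey) cell (a clipped normal approximation is available
behind `resample="normal"`), proportions recomputed, and the *complete*
estimation procedure re-run — including re-selection of the REML smoothing
weight, so the intervals carry smoothing-selection variability; only the
noise whitening stays fixed at the observed data. The 95% interval is the
2.5th and 97.5th percentiles of the replicate distribution, computed with
numpy's inclusive linear-interpolation convention; the point estimate comes
from the
unperturbed data, and cells where it falls outside its own interval are
flagged (`ci_flag`), not hidden. Default 5000 replicates. Replicates that
degenerate (a resampled proportion reaching 1) are dropped and counted;
more than 1% is a hard error. All streams derive from one seed via
`numpy.random.SeedSequence` spawning, so results are bit-reproducible.

Age-standardization (`Σ_a w(a) rate(a)`, direct method) is applied *within
each replicate* before percentiles are taken. The standard-population
weights are user input; when none are supplied the package falls back to
uniform weights over ages 0-19 with a prominent warning, since the US-2000
single-year weights (the conventional choice for this design) are not
bundled.

For comparison against an observed annual incidence panel, the observed
standardized rate is bootstrapped nonparametrically by resampling calendar
years with replacement within each (stratum, age) cell; relative errors
`100 (E - O)/O` pair the prevalence-bootstrap draws of E with the
year-bootstrap draws of O. The panel interface carries rates without
denominators, so no parametric model for O is assumable; resampling years
captures the between-year variation that dominates its uncertainty.

## Synthetic worlds

The generator emulates a two-wave youth-diabetes surveillance design: survey
years 2001 and 2009, single-year ages 0-19, strata = {female, male} x
{NHW, NHB, Hispanic, Other}, observed annual incidence 2002-2008. Incidence
shapes per 100,000 person-years:

* `type1-like`: Gaussian bump, default peak 30 at age 10, width 4.5 y — the
  childhood-onset autoimmune pattern that rises to ~age 10 then declines;
* `type2-like`: logistic rise, default plateau 15, onset age 13, steepness
  1.5 y — near zero before ~10, climbing through adolescence.

Stratum multipliers default to the qualitative pattern reported for US
youth (type 1 highest in NHW and slightly male-dominant; type 2 highest in
NHB/Hispanic females and lowest in NHW). Total population 3.4 million,
split equally over sexes and ages and 40/30/20/10 over NHW/Hispanic/NHB/
Other — denominators of 8,500-34,000 per (sex, race, age) cell, matching
the order of magnitude of the motivating registry. Mortality defaults to 0
with R = 1.

True prevalence comes from the forward solver with burn-in from each
cohort's birth (rates being time-constant, the surface is stationary and
internally consistent at both waves). Case counts are binomial; annual
incident counts are Poisson(denominator x i) — observed rates are ratios of
counts to person-years, and Poisson is the natural sampling model for rate
numerators. `noise_free=True` replaces draws by rounded expectations.

What the generator does *not* emulate: migration, secular trends in
incidence or denominators, misclassification of diabetes type, remission,
or excess mortality. Passing tests therefore demonstrate correct recovery
under the model's own assumptions plus sampling noise — not robustness to
violations of stationarity or closed-population assumptions.

The recovery harness (`recovery_experiment`) simulates many worlds and
reports, per stratum: mean signed relative error of the age-standardized
estimate, RMSE, and 95%-CI coverage of the truth. At the default design
(200 worlds, 500 replicates) worst-stratum bias across both families is
under 8% and coverage sits in the low-to-mid 0.9s; the acceptance test
pins those bounds.

## Numerical and design choices

* Integration step 0.1 y (RK4; error far below the 1e-8 acceptance
  tolerance for the closed-form check at survey-scale rates).
* Percentiles: numpy `method="linear"` (inclusive interpolation) — stated
  because percentile dialects differ.
* Survey gap must be an integer number of years; the stated gap is checked
  against the curves' year labels.
* Negative finite-difference or constraint values are floored at zero with
  warnings, never silently.
* The REML grid spans 1..1e16 multiplicatively; on the whitened scale this
  covers "no smoothing" to "quadratic fit" for all realistic denominators.
* Problem sizes in the validation suite and acceptance script (worlds,
  replicates) are chosen so the full Monte-Carlo evidence regenerates in a
  few minutes on one CPU; the experiment design (denominators, shapes,
  B = 500 at 200 worlds for the pinned bounds) is fixed independently of
  any particular run's outcome.
* Determinism: same seed ⇒ byte-identical outputs; different seeds agree
  within percentile Monte-Carlo error. A two-run consistency check compares
  CI endpoints against twice the standard error of their difference
  (asymptotic percentile SE with a KDE density estimate at the quantile).

## Known limitations

* Incidence is assumed constant over the inter-survey period; with only two
  cross-sections a time trend is not identifiable, and the estimate is the
  period average. Trend estimation needs three or more waves.
* Differential mortality (R ≠ 1) is supported by the forward solver but not
  by the estimator, which inverts the simplified equation; applying it to
  conditions with substantial excess mortality biases incidence downward.
* The boundary age's estimate is an extrapolation and is flagged; users
  should not over-interpret it (deviations at the youngest and oldest ages
  are expected for this class of estimator).
* The smoothed estimator trades a small shape-dependent bias (measured
  under ±8% of the standardized rate at registry-like noise) for a large
  variance reduction; unsmoothed estimates are available by passing
  `smoothness=0`.
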