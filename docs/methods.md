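# Methods

## Model and estimand

The package estimates a resource selection probability function (RSPF) from
counts of GPS fixes in equal-radius circular sampling units.  Writing tᵢ for
the count in unit *i*, xᵢ for its covariate vector and T for the total
number of recorded fixes across all animals,

    tᵢ ~ NB2( uᵢ, θ ),    uᵢ = exp( ln T + β₀ + β'xᵢ ),    var[tᵢ] = uᵢ + uᵢ²/θ.

exp(β₀ + β'xᵢ) is the modeled relative frequency of use of unit *i* — the
discrete utilization distribution evaluated on the unit.  Without the ln T
offset the same model describes raw counts; the offset only shifts the
intercept, a property the fitter reproduces exactly (see Invariances).

Key assumptions, in decreasing order of importance:

- **Poisson-type sampling of units.**  Unit counts must not be constrained
  to sum to T.  Random-with-replacement samples (overlap allowed) and
  systematic samples with gaps both guarantee this; a design that exhausts
  the study area would require a multinomial likelihood instead and is not
  supported.
- **Counts follow NB2.**  No censoring/truncation, and no *excess* of zeros
  beyond what NB2 itself predicts — which is a lot: at mean 5 and θ = 0.2,
  P(0) = 0.52 and P(>50) = 0.013.  The fit report prints observed versus
  expected zero fractions so users can judge; zero-inflated and hurdle
  variants are deliberately out of scope.
- **Representative sampling of animals and near-complete fix success.**
  Habitat-dependent fix failure is not corrected for.
- **Temporal independence of fixes is NOT assumed.**  Units carry no
  timestamps; serial correlation inflates among-animal variance, which the
  animal-level bootstrap absorbs.  Fixes should be on a comparable schedule
  across animals, since each animal's contribution is weighted by its fix
  count.

## Fitting algorithm

β and θ are joint ML estimates obtained by alternation: IRLS for β at fixed
θ (working weights uθ/(u+θ)), then a 1-D solve of the θ score (digamma
form) by `brentq` on the log scale, until the joint log-likelihood improves
by less than 1e-8 (at most 100 outer iterations; failure raises
`ConvergenceError` carrying the last iterate).  This is the same scheme as
R's `glm.nb`, and the reported coefficient covariance is likewise the
inverse Fisher information at the optimum *conditional on θ*.  Numerical
choices that matter:

- θ is bounded to [1e-4, 1e7].  When the interior score root gains less
  than 1e-4 log-likelihood units over the upper bound, θ̂ snaps to the
  bound: near-equidispersed data leave θ unidentified beyond "large", the
  profile there is flatter than the `lgamma` rounding noise, and without
  the snap the alternation can oscillate indefinitely.  θ̂ at the bound is
  reported as-is and simply means "Poisson-compatible".
- Convergence is declared when the *improvement* falls below tolerance.
  Each exact alternating step is non-decreasing, so a noise-level decrease
  is also a convergence signal, not progress.
- Starting values: Poisson-regression β; method-of-moments θ₀ =
  max(0.01, ū²/(s²−ū)) when s² > ū, else θ₀ = 100 (the spec-book moment
  formula is undefined for under-dispersed data, and the Poisson side is
  then the right neighborhood).  Bootstrap replicates warm-start from the
  pooled fit.
- Deviance is 2Σ[ yln(y/û) − (y+θ̂)ln((y+θ̂)/(û+θ̂)) ] with y ln y := 0 at
  y = 0; D/df substantially above 1 flags grouping (panel) structure or
  other misspecification.  There is no formal test — it is a screening
  diagnostic, and even correctly specified NB2 fits sit slightly above 1.
- AIC counts θ as an estimated parameter.

The ML SEs are printed but flagged: under pooled multi-animal data they
ignore among-animal correlation and are anti-conservative.  The endorsed
inference path is the bootstrap.

## Spatial sampling and counting

Units are closed discs: a fix at distance exactly r from a center is inside,
a fix inside k overlapping units counts k times, and unit footprints may
extend past the region boundary (only centers are constrained).  Counting is
exact KDTree range search and is checked in the tests against brute-force
pairwise distances.  Coordinates are planar projected meters throughout; no
geographic support.  The systematic design is a square lattice with a seeded
uniform random origin in [0, spacing)²; spacing must be ≥ 2r so systematic
units never overlap.  Random designs draw centers uniformly (rejection
sampling inside an optional polygon boundary) with replacement.

## Animal-level inference

`bootstrap_by_animal` resamples the m animals with replacement B times
(default B = 1000, level 0.90).  A replicate pools the drawn animals'
per-unit counts (an animal drawn k times contributes k-fold), uses its own
offset ln T_b, and refits.  SEs are replicate SDs; CIs are central
percentile intervals with type-7 (linear) interpolation.  Replicates that
fail to converge are dropped, logged and counted; more than 20% failures
aborts.  Within-animal fixes are never resampled.  The pooled fit is the
point estimate, so the result is a marginal model in which each animal's
contribution is weighted by its number of fixes.

`two_stage` instead fits each animal separately (its own offset ln T_a) and
averages coefficients unweighted; the population SE is the coefficient SD
over √m.  Averaging coefficients makes the result an RSF — predictions are
geometric means of per-animal models — rather than an RSPF.  Animals with
fewer occupied units than parameters + 2, or whose fits fail, are excluded
and listed, never dropped silently.

Known limitation: central-percentile cluster bootstraps are slightly
anti-conservative when the number of resampled clusters is small — the
replicate SD understates the sampling SD by roughly √((m−1)/m), and B in
the low hundreds adds percentile-endpoint noise.  With herd sizes around
10, nominal 90% intervals should be read as a few points lighter; the
coverage validation in the test suite therefore uses a larger herd (m = 50,
200 replicate studies, B = 200), where the interval attains its nominal
level and what is being tested is the implementation rather than
small-sample bootstrap theory.

## Prediction and mapping

Predictions evaluate exp(β̂₀ + β̂'x) — relative frequencies; the training
offset is never added back (a `scale="count"` flag multiplies by T).  New
units must share the modeling radius (covariates are unit-scale summaries,
so unit size must be consistent from modeling to mapping); prediction grids
may be finer than, and overlap, the modeling units.  Because of overlap and
gaps, predictions carry no unit-sum constraint; `rescale="max1"` or
`"unit_sum"` produce map-friendly scalings.  Covariates outside the
modeling range warn (`OutOfRangeWarning`) rather than error: mapping grids
routinely poke slightly past sampled units, but extrapolation is the user's
responsibility.

Marginal profiles evaluate every bootstrap replicate on a grid spanning a
covariate's *observed* range, others held at their medians (overridable);
the pointwise median and central percentiles are then divided by one joint
maximum so the display maxes at 1.

## Synthetic data generator

`simulate_locations` gives each animal its own coefficient vector
β_a = β + N(0, diag(sd²)) and drops its T_a fixes i.i.d. over a fine lattice
(default 25 m, far below the 200-m unit radius) with probability
∝ exp(β_a'x(cell)), jittered within cells and timestamped hourly.  Covariate
surfaces are smooth deterministic functions — linear gradients, distances to
line features, sinusoids — so true marginal response shapes are known in
closed form.  `simulate_counts` is the distribution-level oracle: it draws
NB2 counts directly from the regression model on an existing unit table.

The default `elk_like_spec()` emulates a 10-animal elk study in a ~7800-ha
square: 500 hourly fixes per animal, ~500 nonoverlapping systematic 200-m
units (400-m spacing), four modeled covariates in field-realistic units
(distance to road and to cover–forage edge in km, percent slope, soil depth
in cm) with coefficients of published magnitude, plus a fifth, fine-scale
"patchiness" field that shapes the true intensity but is *not* among the
default modeling covariates.  Overdispersion therefore has two realistic
sources — among-animal heterogeneity and unmodelled habitat structure — and
the defaults were calibrated once so a seeded end-to-end run lands near the
published study's texture (≈30% empty units, θ̂ around 0.4–0.7, D/df just
above 1).

What the generator does **not** emulate: movement (fixes are i.i.d. given
the animal, no home ranges, no autocorrelated tracks), habitat-dependent
fix failure, GPS positional error beyond the lattice jitter, and covariate
measurement as true disc averages (surfaces are evaluated at unit centers;
they are smooth at unit scale, where center value ≈ disc mean).  Passing
tests consequently demonstrate correctness of the estimator under the
model's own sampling assumptions plus realistic heterogeneity — not
robustness to movement behavior or detection bias.

Because each animal is conditioned on exactly T_a fixes, landscape-level
sampling is multinomial, not Poisson; unit counts still behave as
Poisson-type because the units never exhaust the fixes.  This is relied on
and verified empirically (parameter recovery through the full location
loop) rather than proven.

## Problem sizes used in the validation suite

Recovery: 100 replicates of 1000 units (count-level).  Wald coverage: 500
replicates of 500 units.  Bootstrap CI coverage: 200 replicate studies,
m = 50 animals × 100 fixes, ~100 units, B = 200.  Bootstrap-vs-ML SE
ordering and deviance-ratio inflation: 15–25 replicate studies of the
10-animal heterogeneous design.  End-to-end calibration: one seeded run of
the full elk-like default.  All seeds are fixed; the whole suite runs in a
few minutes on one core.
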