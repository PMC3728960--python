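# nbrspf — negative-binomial resource selection from GPS count data

`nbrspf` estimates how animals select habitat from GPS telemetry by modeling
the **intensity** of use rather than a used/available binary response.  The
study area is covered with equal-size circular sampling units, the number of
GPS fixes falling in each unit is counted, and the counts are related to the
units' habitat covariates with negative-binomial (NB2) regression.  The
approach is aimed at wildlife ecologists and biostatisticians working with
modern high-frequency collar data: it is unbiased under temporally
correlated fixes, handles very large location datasets at trivial
computational cost, and treats the individual animal — not the fix — as the
experimental unit for inference.

## The model

For sampling unit *i* with covariates x₁ᵢ…x_pᵢ and fix count tᵢ,

```
E[tᵢ] = exp( ln T + β₀ + β₁x₁ᵢ + … + β_p x_pᵢ ),    var[tᵢ] = uᵢ + uᵢ²/θ
```

where T is the total number of recorded fixes.  The offset ln T converts
counts to **relative frequencies**: exp(β₀ + Σβⱼxⱼᵢ) estimates the
probability that any one fix lands in unit *i* — a resource selection
*probability* function (RSPF), a discretized utilization distribution.  θ is
the NB2 dispersion (smaller θ = more overdispersion; θ → ∞ recovers
Poisson).  β and θ are estimated by maximum likelihood, alternating IRLS for
β with a 1-D likelihood solve for θ.

Because fixes from one animal are correlated, ML standard errors are
anti-conservative.  Population-level uncertainty comes from bootstrapping
**animals**: resample the m collared animals with replacement, re-pool,
re-count, refit (with each replicate's own offset ln T_b); the SD of the
replicate coefficients is the SE and the central 90% of their distribution
is the CI.  A two-stage estimator (per-animal fits, coefficients averaged)
is provided as the classical alternative; effects are interpreted through
rate ratios 100·(exp(βΔx) − 1) and marginal response profiles with bootstrap
envelopes.

No elk dataset ships with the package; `nbrspf.simulate` generates GPS
studies with known selection coefficients, among-animal heterogeneity and
NB2-level overdispersion, emulating a published 10-elk study in a ~7800-ha
enclosure (≈500 fixes/animal, ~500 nonoverlapping 200-m units).

## Worked example

```python
from nbrspf import bootstrap_by_animal, count_locations, fit_nb2
from nbrspf.simulate import elk_like_spec, make_systematic_units, simulate_locations

spec = elk_like_spec()                            # 10 animals, 500 fixes each
units = make_systematic_units(spec, seed=1)       # 484 systematic 200-m units
locs, truth = simulate_locations(spec, seed=1001)
counted = count_locations(units, locs)
res = fit_nb2(counted, offset_total=len(locs))
print(res.summary())
```

```
NB2 resource selection (probability) function
==============================================================
No. units:    484    Residual df:    479
Offset ln(T), T = 5000 (predictions are relative frequencies)
Log-likelihood:    -1275.165    AIC:    2562.33
theta (dispersion):   0.4436
Deviance:     514.02    D/df:  1.073
Zero fraction  observed: 0.318  expected under fit: 0.341
--------------------------------------------------------------
                                coef     ML SE       z
const                        -9.4075    0.3474  -27.08
dist_road                     0.3612    0.1135    3.18
slope                         0.0047    0.0072    0.65
dist_edge                    -0.2861    0.1139   -2.51
soil                          0.0208    0.0018   11.33
```

About a third of units are empty (0.318) — unremarkable for an NB2 with
θ̂ ≈ 0.44, which itself expects 34% zeros at these fitted means.  D/df of
1.07 signals mild residual grouping, as expected for pooled multi-animal
("panel") counts.  Animal-level inference:

```python
boot = bootstrap_by_animal(locs, units, B=1000, seed=7)
print(boot.summary())
```

```
Animal-level bootstrap of the NB2 RSPF (1000 replicates, 0 failed; 10 animals; 90% percentile CIs)
==============================================================================
                               coef    ML SE  boot SE    CI lo    CI hi
const                       -9.4075   0.3474   0.7645 -10.8818  -8.4662
dist_road                    0.3612   0.1135   0.2257   0.0509   0.7690
slope                        0.0047   0.0072   0.0036  -0.0019   0.0093
dist_edge                   -0.2861   0.1139   0.1208  -0.5001  -0.1056
soil                         0.0208   0.0018   0.0038   0.0158   0.0281
```

Bootstrap SEs are roughly twice the ML SEs for most coefficients — the
among-animal variation the pooled fit ignores.  `rate_ratio(0.0208)` turns
the soil coefficient into "+2.10% expected use per cm of soil depth", and
`boot.marginal_profile("soil")` returns the median response curve with its
90% envelope, scaled to a maximum of 1, for plotting.

A command line mirrors the library:
`nbrspf simulate | sample-units | count | fit | bootstrap | predict | marginal`
(see `nbrspf --help`); every subcommand is seed-reproducible and writes
CSV/JSON only.

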