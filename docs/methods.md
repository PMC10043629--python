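# Methods

## Model and estimator

The package treats need of long-term care as an irreversible-by-default
three-state process: care-free (healthy), in need of care (ill), dead.
Transitions are the incidence rate `i(t, a)` (care-free → care), the
care-free mortality `m0(t, a)`, the care mortality `m1 = R · m0` with
mortality rate ratio `R`, and optionally a remission rate `r` (care →
care-free).  The prevalence `p(t, a) = C/(S + C)` of the care state obeys the
transport equation along aging cohorts,

    (∂t + ∂a) p = (1 − p) [ i − m p (R − 1) / (p (R − 1) + 1) ] − r p,

where `m = m0 (1 − p) + m1 p` is the all-cause mortality of the **total**
population — the quantity a period life table publishes.  The term
`m p (R − 1)/(p (R − 1) + 1)` equals `p (1 − p)(m1 − m0) / (1 − p)`, i.e. the
selective removal of the ill.  Rearranged for `i`:

    i = ((∂t + ∂a) p + r p) / (1 − p) + m p (R − 1) / (p (R − 1) + 1).

This is an exact algebraic identity, not an approximation: `verify_pde_consistency`
checks it to 1e−12 over random admissible inputs, and negative estimates are
reported with a `negative_estimate` flag rather than clipped — a negative
value diagnoses declining cohort prevalence that the assumed mortality
surplus cannot explain.

For `p < 1` and `R > 0` the denominator `p (R − 1) + 1` exceeds `1 − p > 0`,
so the estimator is defined on the whole admissible domain; the domain guard
for a non-positive denominator is defensive only.

## Prevalence surface

Observed group prevalences are logit-transformed (after clipping to
`[1e−12, 1 − 1e−12]`; clipped rows are reported) and regressed on calendar
year (centred at `t_ref = 2015`, the middle of the 2011–2019 reporting
period) and a representative age per group, separately by sex, by ordinary
least squares (optionally population-weighted).  Representative ages default
to interval midpoints; the broad and open groups of the registry layout get
documented constants (<15 → 7.5, 15–59 → 37.5, 90+ → 92.5), all overridable.
Predictions are invariant to `t_ref` (tested).  The cohort derivative has
the closed form `p (1 − p)(β_t + β_a)` under the fitted surface; a central
finite difference of the prediction serves as the independent test oracle.

The regression deliberately mirrors the published method (one linear age
term, no interactions, no splines).  Which groups enter the fit is not fixed
by that method; the package default for recovery experiments keeps the
5-year groups with lower bound ≥ 40 and drops the open-ended 90+ group,
whose representative age is a convention rather than a measurement.  The
`estimate` CLI fits all groups unless `--min-fit-age` is given.

## Mortality input

The mortality table holds all-cause rates per person-year by calendar year,
sex and single age.  Queries between tabulated years/ages are bilinear;
queries outside the tabulated hull fail loudly — the data give no basis for
extrapolation.  All rates are per person-year internally; the ×1000 scaling
exists only in the output table.

## Synthetic data and what it does (not) emulate

Two ground-truth families drive the generator:

* **Gompertz regime** — incidence `i(a) = i0 e^{β_i a}` and care-free
  mortality `m0(a) = α e^{γ a}`, both time-invariant.  Defaults (chosen once
  as a realistic configuration: crossover of the sexes' incidence near age
  65, women's background mortality below men's, adult rates between ~1 and
  ~150 per 1000 PY):
  female `i0 = 5.2e−6, β_i = 0.110, α = 2.5e−5, γ = 0.100`,
  male `i0 = 1.0e−5, β_i = 0.100, α = 5.0e−5, γ = 0.095`, `R = 3.2`, `r = 0`.
* **Logit-linear regime** — the prevalence surface itself is chosen
  logit-linear in `(t, a)` and the incidence that generates it is derived by
  inverting the transport equation; feeding that incidence forward
  reproduces the surface exactly, so the regression is well-specified and
  pipeline errors isolate numerics.

The **compartment solver** integrates `S' = −(i + m0) S + r C`,
`C' = i S − (R m0 + r) C` along each birth cohort with classical fixed-step
RK4 (default step 0.05 y; the spec of the solver requires ≤ 0.25).  Halving
the default step changes the surface by < 1e−8 and the error contracts ~16×
per halving (tested).  The integration mesh is refined to land exactly on
requested evaluation ages, so fractional ages (used for finite-difference
cohort derivatives at h = 1e−3) are solver-exact rather than interpolated.

The **microsimulation** samples individual histories from the same hazards,
piecewise constant on a 0.05-year grid (midpoint evaluation), by exact
inversion of the piecewise-linear cumulative hazard — equivalent to per-step
competing-risk sampling but vectorisable to 200 000 persons × ~100 birth
cohorts in seconds.  It is the stochastic oracle for the solver: grouped
prevalences agree within 3 binomial standard errors at that size (tested).

**Table emission.**  Single-year age classes are evaluated at their band
midpoints (`a + 0.5`), so the person-weighted mean over the classes of a
5-year group is consistent with the group's midpoint representative age;
mortality rows are emitted at exact integer ages.  Group prevalence is the
survivorship-weighted mean of `p` over member classes; populations are equal
birth cohorts of 1 000 000, so emitted counts embed realistic attrition but
no migration, no cohort-size differences, and none of the registry's
definitional level shifts (care-reform reclassifications etc.).  Passing
recovery tests therefore certify the estimator and regression machinery, not
robustness to those real-data artifacts.

## Recovery experiments and measured error

`recovery_experiment` runs tables → regression → inversion with the true `R`
and `r` and reports per-age relative errors of the recovered incidence.

* Logit-linear truth, single-year age classes, biennial tables 2011–2019,
  ages 50–90: max relative error ≈ 0.2 % (residual sources: count rounding
  at cohort size 1e6 and within-band aggregation).  Under the 5-year
  registry grouping the same truth shows ≈ 4 % — pure grouping bias of
  midpoint age assignment.
* Gompertz truth under the 5-year registry grouping, ages 60–85: maximum
  relative error ≈ 18 % (mean ≈ 11 %).  The cause is structural: with
  `R = 3.2` the prevalence approaches the equilibrium where new cases balance
  excess deaths, so logit `p` is strongly concave above ~age 85 and one
  global age slope under-states the cohort derivative at 60–70 while
  over-stating it at 85+.  A systematic scan over fit windows
  (50/55/60–85/90/∞), OLS vs population weighting, single-age vs 5-year
  grouping and midpoint vs person-weighted-mean representative ages puts the
  attainable minimum at ≈ 17 %; the corresponding acceptance test encodes a
  15 % bound and is expected to fail by that margin.  This quantifies the
  misspecification error carried into real-data estimates wherever the true
  incidence is exponential in age.
* Estimating with the wrong assumptions biases the estimate in the
  documented directions: `R` too low → high-age incidence underestimated;
  ignoring true remission (`r = 0` when `r > 0`) → uniform underestimation,
  i.e. the default estimate is a lower bound (both sign-tested).

## Scenario defaults

`ScenarioConfig` defaults to `R ∈ {3.2, 1.17}` (the literature extremes for
care vs non-care mortality), `r = 0`, evaluation year 2015 and integer ages
50–90 — the reporting window of the estimates.  `R` and `r` are scenario
constants over age, but the low-level estimator accepts age-varying arrays
for sensitivity analyses.

## Numerical choices and edge cases

* Logit clipping ε = 1e−12: zero counts (young groups) must not crash the
  fit; the affected rows are surfaced as warnings.
* Fit requires ≥ 3 points and a rank-3 design (at least two distinct years
  and two representative ages); anything less is a hard `FittingError`.
* Prevalence is recomputed from counts whenever both counts are present;
  a stated prevalence deviating by more than `0.5/n_pop` triggers a warning
  (counts are primary).
* Mortality tables must form a full year × age grid per sex (rectangular)
  for bilinear interpolation; one-year tables degrade to linear-in-age
  interpolation with exact-year matching.
* Microsimulation seeds are explicit arguments; no global RNG state.

## Known limitations

* The logit-linear surface cannot represent prevalence saturation (see the
  Gompertz recovery numbers above); estimates at the oldest ages inherit
  this bias.
* No uncertainty intervals: sampling error of the registry counts is
  negligible at national scale, and the dominant uncertainty — the unknown
  `R` — is bracketed by scenarios instead.
* Care-grade stratification, projection of future prevalence, and emulation
  of registry definitional changes are out of scope.
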