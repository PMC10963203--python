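# Methods

This note records the statistical model the package implements, the
choices made where the method left room, and what the synthetic studies do
and do not establish.

## Sampling and response model

The population `U` of `N` units is partitioned into `L` domains `U_a` of
size `N_a`.  Each unit carries a *fixed* response stratum — respondent or
non-respondent — so `N_a = N_1a + N_2a` are constants of the population,
not realizations.  A replicate draws an SRSWOR sample of size `n`,
partitions it by stratum into `s1` (size `n1`) and `s2` (size `n2`), and
draws an SRSWOR subsample `s2r` of size `n2r = min(n2r_target, n2)` from
`s2`, giving the subsampling factor `k = n2/n2r ≥ 1`.  Design weights are
`d_i = N/n` for all sampled units, times `k` for subsampled
non-respondents.  The uncalibrated Hansen–Hurwitz total
`Σ_{s1} d y + Σ_{s2r} d k y` is design-unbiased for `Y` for any fixed
subsample size, a property the test suite verifies by Monte Carlo at a
3-standard-error tolerance.

Response/non-response sizes vary hypergeometrically across replicates
(they are not conditioned to fixed values); `n2r_target` is fixed per
study configuration and capped at the realized `n2`.  A replicate with
`n2 = 0` keeps only the respondent term and respondent constraint and is
counted as degenerate.

## Calibration and the four weight systems

Per domain `a`, weights are calibrated so the weighted auxiliary totals of
the *full* respondent sample and *full* non-respondent subsample hit that
domain's stratum targets `X_1a`, `X_2a` (indirect, synthetic-type
estimation; a `direct=True` mode restricts the sums to the domain's own
units).  The chi-square-distance solution is
`t_i = d_i (1 + l q_i x_i)` with the closed-form multiplier
`l = (X − Σ d x)/(Σ d q x²)`:

* `q = 1/x` collapses to the ratio weight `t_i = d_i X/Σ d x`;
* `q = 1` is GREG; both are verified in tests against independently coded
  closed forms at 1e-10 relative tolerance.

The exponential system `t_i = d_i exp(l x_i)` and power system
`t_i = d_i η^{x_i}` treat the q-constants implicitly: the calibration
constraint `Σ d x exp(l x) = X` is solved directly for the multiplier.
Because `η = e^l` is a bijection, **the exponential and power systems are
the same one-parameter family under the exact solve and produce identical
weights and estimates**; the package solves once and reports both.  Any
daylight between them in other accounts of this method can only come from
truncating the series expansions of the implicit q-constants, which this
package deliberately does not do — the series are circular in the unknown
multiplier, and solving the constraint is the executable reading.

### Numerics

The constraint function `f(l) = Σ d x e^{lx}` is strictly increasing and
convex for positive `d`, `x`, so Newton–Raphson from `l = 0` converges
globally; `x` is rescaled by its maximum inside the solve to avoid
overflow on skewed auxiliaries, and a bisection fallback on
`l·x_max ∈ [−745, 745]` (the float64 exp range) guards non-finite steps.
Convergence is declared at relative constraint residual ≤ 1e-10 with an
iteration cap of 100.  The solver is cross-checked against a brute-force
bisection oracle in the tests.

Linear (GREG) calibration can produce negative weights when the domain
target is far below the full-sample weighted total — routine in indirect
estimation on skewed data.  Negative weights are permitted (chi-square
calibration does not bound weights) but counted, and the per-cell
`negative_weight_rate` is reported.  The multiplicative systems keep
weights positive by construction.  The closed-form multiplier is rejected
only when its denominator is exactly zero or non-finite; a negative
denominator — possible when chaining calibrations whose base weights are
negative GREG weights — is algebraically valid and retained.

## Two-phase (double) sampling

When `X_1a`, `X_2a` are unknown: phase 1 draws `round(f · N_a)` units per
domain (default `f = 0.6`), with exact design weight `N_a/n'_a` per unit,
realizes response, and subsamples non-respondents.  The estimated targets
are the phase-1 Hansen–Hurwitz domain totals `x'_1a`, `x'_2a` of the
auxiliary.  Phase-1 weights (over the full phase-1 respondent sample and
non-respondent subsample) are calibrated to these targets under the chosen
weight system.  Phase 2 draws an SRSWOR subsample of the whole phase-1
sample (conditional weight `n'/n''`), realizes response and subsampling
again, and calibrates the chained weights — phase-1 calibrated weight ×
conditional design weight (× phase-2 subsampling factor for
non-respondents) — to the same targets.  The same auxiliary variable is
used at both phases.

Two design choices deserve note:

* **Carried weights as a function.**  A phase-2 non-respondent need not
  belong to the phase-1 non-respondent *subsample*, so its realized
  phase-1 calibrated weight may not exist.  Phase-1 calibration is
  therefore treated as defining a weight function of `x` (design weight ×
  solved multiplier term) which is evaluated at any phase-2 unit.  For
  respondents this coincides identically with the realized weight, since
  phase-2 respondents nest inside phase-1 respondents under the fixed
  strata.
* **The uncalibrated two-phase base estimator** weights a phase-2
  respondent by `(N_a/n'_a)(n'/n'')` and a subsampled phase-2
  non-respondent additionally by the *phase-2* factor `k'' = n''_2/n''_2r`
  only: the unit's y-observation never passed through phase-1
  subsampling, so `k'` does not belong in its inclusion probability.  This
  estimator is close to unbiased in the simulations (ARB ≈ 1 %), which is
  the check that pinned the construction down.

A domain with an empty phase-1 respondent stratum (or zero estimated
target) is flagged non-estimable for that replicate and counted; the batch
continues.

## Monte Carlo engine

Metrics per (estimator, domain) over `S` replicates: `ARB =
100·|mean(T_s) − Y_a|/Y_a`, `SMSE = mean((T_s − Y_a)²)`, `SRSE =
100·sqrt(SMSE)/Y_a`.  Both ARB and SRSE are invariant to rescaling
estimates and truth by a common factor (tested).  Replicate randomness
comes from substreams spawned from the master `SeedSequence`, so runs are
deterministic given the seed and safe to parallelise.  Failed solver cells
drop that (estimator, domain, replicate) value only and are counted.

Default replicate counts are 2000 (single-phase) and 1000 (two-phase) —
chosen as the package's desk-scale defaults; larger counts are a config
field away and change nothing structurally.

## Synthetic populations

The generator emulates the study population the packaged `table1.csv`
fixture summarises: 6 domains of 48/32/38/41/15/29 units (203 total), 30 %
of each domain assigned once (seeded permutation) to a fixed
non-respondent stratum, auxiliary `x` lognormal with log-sd 1.0 (median
about 1000 with a long right tail), and `y = βx·ε` with `β = 1.8`
(roughly the fixture's aggregate `Y/X` ratio) and mean-one multiplicative
lognormal noise of relative scale 0.15.  When target totals are supplied,
`x` and `y` are rescaled multiplicatively per (domain, stratum) so the
stratum totals match exactly — this preserves the shape of the
distribution while pinning the calibration targets and truth to the
printed table.

What this emulates, and what it does not: the generated population has the
printed totals, skewness, domain structure and response rates of the study
data, but the unit-level values and the mechanism designating
non-respondents are synthetic (random within domain).  In the source data
non-response could correlate with size; if so, real-data error levels
would differ from the synthetic ones.  Passing simulations therefore
establish the *relative* behaviour of the weight systems under the stated
structure (e.g. power/exponential SRSE at or below GREG's in most domains,
poor precision in the smallest domain), not the specific error magnitudes
of any particular real survey.

## Known limitations

* Only unit non-response is modelled; item non-response is out of scope.
* First-stage design is SRSWOR (per-domain SRSWOR at phase 1); no
  unequal-probability or stratified first stages.
* No analytic variance estimators for single estimates: evaluation is by
  simulation, matching the method's own empirical treatment.
* The calibrated indirect estimators are design-biased; the simulations
  quantify, not remove, that bias.
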