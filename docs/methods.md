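# Methods

## Model and assumptions

`previnc` models one chronic disease in a closed population (no
migration) with irreversible transitions Healthy → Diseased,
Healthy → Dead, Diseased → Dead. Nobody is born diseased
(`C*(t, 0) = 0`), and the state densities are assumed smooth enough for
the balance equations to hold classically. The three hazards are the
incidence `i(t, a)`, the mortality of the healthy `m0(t, a)` and the
mortality of the diseased `m1(t, a, d)`, where `d` is time since
disease onset. All rates are per person-year; internal calendar time is
measured in years since a configurable origin (1960 for the shipped
dementia model), and the experiment drivers convert calendar years.

Rates are represented log-linearly, `exp(β0 + β_age·a + β_time·t)`,
with an optional onset age below which the rate is exactly 0. This
Gompertz-type family covers the classical demographic approximations
(exponential rise of mortality with age, geometric secular decline) and
log-linear late-life disease incidence. Rates are extrapolated outside
any fitted range — in particular to calendar times before the origin,
which cohort integrals of old ages may touch — rather than clamped.
The diseased mortality is either `R(d)·m0(t, a)` with a right-continuous
step function `R` (`DurationProfile`; the paper-free way epidemiology
reports excess mortality as a mortality rate ratio by years since
diagnosis), or an arbitrary callable of `(t, a, d)`.

## Forward problem

Two independent routes compute the age-specific prevalence, and their
agreement is part of the test suite.

**Cohort integral formula.** The closed-form solution expresses the
diseased pool at `(t, a)` as an integral over the onset offset `δ`: a
contribution `i(t−δ, a−δ)` of new cases, discounted by healthy survival
up to onset and by the cumulative diseased hazard
`M1(t, a, δ) = ∫0^δ m1(t−δ+τ, a−δ+τ, τ) dτ` since onset. The
prevalence is the ratio of this integral to the total surviving cohort.
Numerical choices:

* The birth-cohort size is normalised to 1: prevalence is a ratio in
  which it cancels; absolute case counts are out of scope.
* The onset integral runs over `δ ∈ [0, a − a_min]`, where `a_min` is
  the incidence onset age, and all survival factors are normalised at
  `a_min`: survival below the onset age is a common factor of numerator
  and denominator and cancels exactly, so `m0` is never evaluated below
  `a_min` inside the prevalence (a regression test adds an arbitrary
  hazard below the onset age and asserts bit-identical prevalence).
* All one-dimensional integrals use adaptive **Romberg quadrature**
  (trapezoidal refinement with Richardson extrapolation, stop when two
  successive diagonal entries agree to tolerance). Defaults: relative
  tolerance 1e-8, absolute 1e-12, at most 22 refinements; with these
  the prevalence values are stable to well beyond 7 decimals, and
  tightening by 10× changes no 7th-decimal digit of the study outputs
  (asserted in the tests). Non-convergence raises a `NumericalError`
  carrying the best estimate.
* The inner cumulative hazards of one birth cohort are cached on a
  shared dyadic age grid: cumulative Simpson sums refined by doubling
  until stable to tolerance (plus one safety doubling), then monotone
  (PCHIP) interpolation. For step-function `R(d)` the duration hazard
  telescopes into differences of the cached cumulative `m0`, split at
  the profile breakpoints; the outer integral is likewise split there,
  since the integrand has derivative kinks at the breakpoints and
  Romberg acceleration assumes smoothness. An arbitrary `m1(t, a, d)`
  falls back to one Romberg integral per outer node.
* If the healthy-survival term of the denominator underflows to 0 the
  prevalence is numerically indistinguishable from 1 and the model
  assumptions have broken down; a `NumericalError` is raised instead of
  returning 1.

The duration-averaged diseased mortality `m1*(t, a)` — the
`C`-weighted mean of `m1` over durations, 0 when the diseased pool is
empty — reuses the same onset-integral machinery, with the step
profile evaluated at panel midpoints (so the right-continuity jumps at
breakpoints never sit inside a quadrature panel).

**Characteristic transport equation.** Along `t − a = const` the
prevalence obeys `dp/da = (1−p)(i − p(m1* − m0))` with `p = 0` at the
start age. The solver is classic fixed-step RK4; the target step
(default 0.05 years) is rounded so that it divides the span exactly.
The start age defaults to the incidence onset age: incidence is zero
earlier, so the solution is identically zero there and any earlier
start gives the same result to solver resolution (asserted at 1e-5).
Excursions of `p` outside `[0, 1]` beyond 1e-9 raise; smaller ones are
clipped. Step-halving tests fit a convergence order ≥ 3.5 on the
dementia example, and the endpoint values agree with the integral
formula to ~1e-12 (the acceptance property asserts 1e-6).

When `m1` depends on duration, the equation needs `m1*`, which itself
depends on the duration distribution of the prevalent cases. The
package breaks this circularity by sourcing `m1*` from the closed-form
cohort solution: it is precomputed on a 1-year age grid along the
characteristic (with the duration-zero limit at the start age, where
the pool is empty) and PCHIP-interpolated to the RK4 nodes. `m1*` is a
smooth, slowly varying hazard, and the resulting prevalence matches
the integral formula to ~5e-7 on the dementia variants tested.

**General-mortality form.** When only the whole-population mortality
`m = p·m1* + (1−p)·m0` and the relative mortality `R = m1*/m0` are
available (life tables plus a disease-specific rate ratio), the same
characteristic equation is driven by
`dp/da = (1−p)(i − m·PAF(p, R))` with the population attributable
fraction `PAF = p(R−1)/(p(R−1)+1)`. Reconstructing `m` from a base
solution and feeding it back reproduces that solution to 1e-6
(self-consistency test).

## Inverse problem: incidence from two cross-sections

Solving the transport equation for `i` gives
`i = (∂t+∂a)p/(1−p) + p(m1* − m0)`, evaluated at the survey midpoint
`t̃ = t0 + Δ/2`. The two survey curves straddle the midpoint along the
characteristic, so

* `p(t̃, a) ≈ ½[p(t0+Δ, a+Δ/2) + p(t0, a−Δ/2)]`, and
* `(∂t+∂a)p(t̃, a) ≈ [p(t0+Δ, a+Δ/2) − p(t0, a−Δ/2)]/Δ`.

Both steps are exact when `p` is affine in `(t, a)` (asserted on a
constructed affine surface); otherwise their error is of order
`Δ²·curvature`. Design choices:

* The estimator requires `a−Δ/2` and `a+Δ/2` to be grid points of the
  respective surveys, and by default outputs exactly the admissible
  interior ages. Monotone interpolation for off-grid ages exists behind
  an explicit flag, default off, so no silent interpolation error is
  introduced.
* Negative incidence estimates are reported with a warning flag, not
  clamped — they diagnose inconsistent inputs.
* The survey lag is inferred from the two survey times; a non-positive
  lag is an error. No smoothing of the input prevalence is performed;
  handling of sampling noise is out of scope.

## The simulated study (synthetic-data generator)

`ExperimentSpec` defines the default study: the dementia-in-German-males
model (`m0 = exp(−9.0 + 0.085a − t·ln 1.01)` since 1960, incidence
`exp(−12.8 + 0.11a)` from age 50, constant relative mortality 2.63 —
the 6-year post-diagnosis average mortality rate ratio reported for a
comparable English cohort), surveys in 2010 and 2015 (lag Δ = 5), ages
60 to 100 in steps of 2.5. These constants are the study conditions,
not tuning knobs. With this geometry the survey stencils align with the
grid (2.5 = Δ/2), the recovery runs at 15 interior ages 62.5…97.5, and
no rate is ever evaluated before calendar year 1960. The generator
produces noise-free prevalence curves: it emulates the *systematic*
error of the estimator (the two linearization steps), not sampling
variability, survey nonresponse or diagnostic misclassification — so a
passing recovery test bounds the method error only, and says nothing
about sampling error in real surveys (bootstrap/confidence intervals
are out of scope).

The duration study replaces the constant ratio by a step profile
`R(d)` when *generating* the data while the estimator still assumes a
duration-free ratio, quantifying the misspecification error. Supplying
the exact `m1*` from the forward model instead removes that error
(oracle test). The package ships no specific year-by-year `R(d)`
values; users with such data pass their own profile.

## Known limitations

* The finite-difference estimator assumes the prevalence is locally
  near-linear over the survey lag. When the incidence hazard is so
  large that the cumulative incidence over `Δ/2` years is of order 1
  (roughly `i·Δ/2 ≳ 0.5`, i.e. prevalence saturating towards 1 between
  the surveys), the linearization breaks down and relative errors grow
  without bound; the estimator reports these estimates unclamped. For
  epidemiologically realistic late-life hazards (up to ~0.2 per
  person-year at the oldest ages) recovery errors stay below ~2%.
* `m1*` inside the transport equation is taken from the closed-form
  cohort solution; in applications where the duration distribution is
  unknown, a surveyed `m1*` must be supplied and its misspecification
  propagates as shown by the duration study.
* No migration, no remission (Diseased → Healthy), no covariates
  beyond `(t, a, d)`, no rate fitting to registry data, no
  nonparametric hazards, no uncertainty quantification.
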