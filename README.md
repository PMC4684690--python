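# previnc — illness-death modelling of chronic-disease prevalence and incidence

`previnc` implements the irreversible three-state illness-death model
(Healthy → Diseased → Dead, Healthy → Dead) used in chronic-disease
epidemiology, on the two time scales calendar time *t* and age *a*,
plus disease duration *d*. It is aimed at epidemiologists and
biostatisticians who want to

* compute age-specific **prevalence** `p(t, a)` from an incidence rate
  `i(t, a)` and the mortality rates `m0(t, a)` (healthy) and
  `m1(t, a, d)` (diseased) — the *forward* problem — and
* estimate age-specific **incidence** from two cross-sectional
  prevalence surveys a few years apart — the *inverse* problem, which
  replaces lengthy follow-up studies with survey data.

## The model

With `S(t, a)` the healthy and `C(t, a, d)` the diseased-by-duration
population densities, the balance equations are

    (∂t + ∂a) S      = −(m0 + i) S
    (∂t + ∂a + ∂d) C = −m1 C,        C(t, a, 0) = i(t, a) S(t, a)

and the package evaluates the prevalence by two equivalent routes:

1. **Cohort integral formula** (Keiding 1991, *J. Roy. Stat. Soc. A*
   **154**, 371–412): the closed-form solution along birth cohorts,
   `p = C*/(S + C*)`, with all nested cumulative-hazard integrals
   evaluated by adaptive Romberg quadrature to a prescribed accuracy
   (`prevalence_keiding`).
2. **Characteristic transport equation**: along the lines
   `t − a = const`,

       dp/da = (1 − p) (i − p (m1* − m0)),     p(onset age) = 0,

   where `m1*(t, a)` is the duration-averaged mortality of the
   diseased, integrated with fixed-step fourth-order Runge–Kutta
   (`solve_prevalence_pde`). A variant takes the *general* mortality
   `m` of the whole population plus the relative mortality
   `R = m1*/m0` and drives the equation through the population
   attributable fraction `p(R−1)/(p(R−1)+1)`
   (`solve_prevalence_general`).

Solving the transport equation for `i` yields the estimator used on
two surveys at `t0` and `t0 + Δ`:

    i(t̃, a) = [(∂t + ∂a) p] / (1 − p) + p (m1* − m0),   t̃ = t0 + Δ/2,

with the directional derivative and the midpoint prevalence obtained
from the surveys by centred differences along the characteristic
(`estimate_incidence`).

## Worked example: dementia in German males

The shipped configuration `dementia_germany.yaml` encodes a simulation
study: Gompertz mortality of the non-demented
`m0 = exp(−9.0 + 0.085 a − t ln 1.01)` (*t* in years since 1960),
dementia incidence `i = exp(−12.8 + 0.11 a)` for ages ≥ 50, and a
constant relative mortality `R = 2.63` of the demented. The forward
model generates the prevalence in 2010 and 2015 (two simulated
cross-sections), and the estimator recovers the incidence at the 2012.5
midpoint:

```sh
previnc recovery-study --out recovery.csv
```

prints (abridged)

```
       age  true_incidence  calculated_incidence  relative_error_pct
62.5000000       0.0026718             0.0027048           1.2362336
75.0000000       0.0105672             0.0106640           0.9164597
90.0000000       0.0550232             0.0552035           0.3275836
97.5000000       0.1255564             0.1259532           0.3160242
max |relative error| = 1.24% (15 ages); wrote recovery.csv
```

The `true_incidence` column is the generating hazard
`exp(−12.8 + 0.11 a)`; `calculated_incidence` is what the two-survey
estimator recovers from the prevalence curves alone; the last column is
the signed percent error of the recovery, which stays below 2% at every
age — the approximation error of the two finite-difference steps.

The same study with a duration-*dependent* excess mortality
`m1 = R(d) m0` (a step-function `DurationProfile`) is run with
`previnc duration-study`; estimating with a single duration-averaged
ratio then biases the oldest ages downward, which an age-piecewise
assumed ratio counteracts.

Forward curves for any configured model:

```sh
previnc forward --rates dementia_germany.yaml --year 2010 --year 2015 \
    --ages 60:100:2.5 --out prevalence.csv
previnc estimate --cs0 cs2010.csv --time0 2010 --cs1 cs2015.csv \
    --time1 2015 --rates dementia_germany.yaml --out estimates.csv
```

CSV formats: prevalence surfaces `time,age,prevalence`; cross-sections
`age,prevalence`; estimates
`age,incidence,midpoint_prevalence,directional_derivative` — all with
a header row and plain decimal numbers.

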