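"""Irreversible three-state illness-death model for chronic diseases.

The model follows a closed population through the states Healthy (H),
Diseased (I) and Dead (D).  Transitions are governed by three hazard
rates on up to three time scales -- calendar time ``t``, age ``a`` and
disease duration ``d``:

* the incidence ``i(t, a)`` of contracting the disease,
* the mortality ``m0(t, a)`` of the healthy,
* the mortality ``m1(t, a, d)`` of the diseased.

Two complementary computational routes connect these rates to the
age-specific prevalence ``p(t, a)`` (the proportion of a-year-olds who
are diseased at time ``t``):

1. Keiding's integral representation (Keiding 1991, J. Roy. Stat. Soc.
   A 154, 371-412): prevalence as a ratio of cohort integrals over the
   onset time, evaluated here with adaptive Romberg quadrature
   (:func:`prevalence_keiding`).
2. A transport equation along the cohort characteristics t - a = const,

       (d/da) p = (1 - p) * (i - p * (m1_star - m0)),      p(a_min) = 0,

   where ``m1_star(t, a)`` is the duration-averaged mortality of the
   diseased, solved with classic fixed-step Runge-Kutta
   (:func:`solve_prevalence_pde`).  A variant accepts the general
   (whole-population) mortality ``m`` plus the relative mortality
   ``R = m1_star / m0`` instead of the pair (m0, m1)
   (:func:`solve_prevalence_general`).

Inverting the transport equation yields the practical payoff: the
age-specific incidence can be estimated from *two cross-sectional
prevalence surveys* a few years apart, plus mortality information --
no follow-up study is needed (:func:`estimate_incidence`).

The module is organised in the order the method runs:

1. configuration, logging and error types,
2. hazard-rate representations (``rates``),
3. Romberg quadrature and cohort-hazard caches,
4. the forward model (survival, duration hazards, ``m1_star``,
   Keiding prevalence),
5. the characteristic PDE solvers,
6. the two-cross-section incidence estimator,
7. the dementia simulation study and experiment drivers,
8. config-file and CSV I/O.

All library-level functions take calendar time as *years since the
model's time origin* (``IllnessDeathRates.time_origin``); the
experiment drivers and the command line accept calendar years and
convert.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_simpson
from scipy.interpolate import PchipInterpolator

__all__ = [
    "InvalidArgumentError",
    "MissingSupportError",
    "NumericalError",
    "ParametricRate",
    "constant_rate",
    "zero_rate",
    "DurationProfile",
    "IllnessDeathRates",
    "GeneralMortalityRates",
    "QuadratureSettings",
    "DEFAULT_QUADRATURE",
    "romberg",
    "cumulative_duration_hazard",
    "survival_healthy",
    "m1_star",
    "prevalence_keiding",
    "prevalence_surface",
    "PrevalenceSurface",
    "CharacteristicSolverSettings",
    "DEFAULT_SOLVER",
    "solve_prevalence_pde",
    "solve_prevalence_general",
    "attributable_fraction",
    "CrossSection",
    "IncidenceEstimate",
    "midpoint_prevalence",
    "directional_derivative",
    "estimate_incidence",
    "relative_error",
    "ExperimentSpec",
    "ComparisonTable",
    "dementia_rates",
    "dementia_config_path",
    "generate_cross_sections",
    "run_recovery_study",
    "run_duration_study",
    "load_rates",
]

logger = logging.getLogger("previnc")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class InvalidArgumentError(ValueError):
    """An argument violates a precondition of the model."""


class MissingSupportError(InvalidArgumentError):
    """A required age is not on a cross-section's grid."""


class NumericalError(ArithmeticError):
    """A numerical procedure failed to reach the prescribed accuracy.

    Attributes
    ----------
    estimate : float or None
        The best estimate achieved before giving up, when one exists.
    """

    def __init__(self, message: str, estimate: float | None = None):
        super().__init__(message)
        self.estimate = estimate


def _require_finite(name: str, *values) -> None:
    for v in values:
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError(f"{name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# Hazard-rate representations
# ---------------------------------------------------------------------------

#: A hazard of calendar time (years since origin) and age, per person-year.
RateFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ParametricRate:
    """Log-linear (Gompertz-type) hazard ``exp(b0 + b_age*a + b_time*t)``.

    The family covers the classical demographic approximations used for
    all-cause mortality (exponential rise with age, geometric secular
    decline) and for the incidence of dementia and other late-life
    chronic diseases.

    Parameters
    ----------
    beta0 : float
        Log-rate intercept (dimensionless).
    beta_age : float
        Slope per year of age.
    beta_time : float
        Slope per calendar year; e.g. ``-ln(1.01)`` encodes a secular
        mortality decline of 1% per year.
    min_age : float
        Ages below this evaluate to a rate of exactly 0 (the disease
        cannot be contracted, or the rate model does not apply).
    """

    beta0: float
    beta_age: float
    beta_time: float = 0.0
    min_age: float = 0.0

    def __post_init__(self):
        _require_finite("ParametricRate coefficients",
                        self.beta0, self.beta_age, self.beta_time, self.min_age)
        if self.min_age < 0:
            raise InvalidArgumentError("min_age must be >= 0")

    def __call__(self, t, a):
        t = np.asarray(t, dtype=float)
        a = np.asarray(a, dtype=float)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise InvalidArgumentError("rate arguments (t, a) must be finite")
        out = np.exp(self.beta0 + self.beta_age * a + self.beta_time * t)
        out = np.where(a >= self.min_age, out, 0.0)
        # scalar in, scalar out
        return out[()] if out.ndim == 0 else out


def constant_rate(value: float, min_age: float = 0.0) -> ParametricRate:
    """A rate that is constant in both time scales (``value`` > 0)."""
    if value <= 0:
        raise InvalidArgumentError("constant_rate requires value > 0; "
                                   "use zero_rate for a vanishing hazard")
    return ParametricRate(math.log(value), 0.0, 0.0, min_age)


class _ZeroRate:
    """The identically vanishing hazard (e.g. a disease nobody contracts)."""

    min_age = 0.0

    def __call__(self, t, a):
        out = np.zeros(np.broadcast(np.asarray(t, float), np.asarray(a, float)).shape)
        return out[()] if out.ndim == 0 else out


def zero_rate() -> _ZeroRate:
    return _ZeroRate()


@dataclass(frozen=True)
class DurationProfile:
    """Relative mortality ``R(d)`` as a right-continuous step function.

    ``values[j]`` applies on ``[breakpoints[j-1], breakpoints[j])`` (with
    an implicit first edge at 0) and ``default_value`` beyond the last
    breakpoint.  A profile without breakpoints is a constant, i.e. a
    duration-independent relative mortality.
    """

    breakpoints: tuple[float, ...] = ()
    values: tuple[float, ...] = ()
    default_value: float = 1.0

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)
        if len(bp) != len(vals):
            raise InvalidArgumentError("breakpoints and values must have equal length")
        if any(b < 0 for b in bp) or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise InvalidArgumentError("breakpoints must be >= 0 and strictly increasing")
        if any(v <= 0 for v in vals) or self.default_value <= 0:
            raise InvalidArgumentError("relative-mortality values must be > 0")
        _require_finite("DurationProfile", bp, vals, self.default_value)

    @classmethod
    def constant(cls, value: float) -> "DurationProfile":
        return cls((), (), float(value))

    @property
    def is_constant(self) -> bool:
        return len(self.breakpoints) == 0

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise InvalidArgumentError("disease duration d must be >= 0")
        lut = np.asarray(self.values + (self.default_value,), dtype=float)
        idx = np.searchsorted(np.asarray(self.breakpoints), d, side="right")
        out = lut[idx]
        return out[()] if out.ndim == 0 else out

    def mean_over(self, d0: float, d1: float) -> float:
        """Duration-average of R over ``[d0, d1]`` (e.g. years 1 to 6)."""
        if not d1 > d0 >= 0:
            raise InvalidArgumentError("need 0 <= d0 < d1")
        edges = [d0] + [b for b in self.breakpoints if d0 < b < d1] + [d1]
        total = sum(self(0.5 * (lo + hi)) * (hi - lo)
                    for lo, hi in zip(edges, edges[1:]))
        return total / (d1 - d0)


@dataclass(frozen=True)
class IllnessDeathRates:
    """The rate bundle (i, m0, m1) defining one illness-death model.

    The diseased mortality is represented either multiplicatively, as
    ``m1(t, a, d) = R(d) * m0(t, a)`` with a :class:`DurationProfile`
    ``R`` (the common epidemiological parameterisation), or as an
    arbitrary callable of ``(t, a, d)``.  Exactly one representation
    must be given.

    ``time_origin`` is the calendar year mapped to ``t = 0``; every
    rate is evaluated at years since that origin.
    """

    incidence: RateFunction
    mortality_healthy: RateFunction
    duration_profile: DurationProfile | None = None
    mortality_diseased: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None
    time_origin: float = 1960.0

    def __post_init__(self):
        if (self.duration_profile is None) == (self.mortality_diseased is None):
            raise InvalidArgumentError(
                "exactly one of duration_profile and mortality_diseased must be set")

    @property
    def incidence_min_age(self) -> float:
        return float(getattr(self.incidence, "min_age", 0.0))

    @property
    def duration_independent(self) -> bool:
        return self.duration_profile is not None and self.duration_profile.is_constant

    def m1(self, t, a, d):
        """Mortality of the diseased at time t, age a, duration d."""
        d_arr = np.asarray(d, dtype=float)
        a_arr = np.asarray(a, dtype=float)
        if np.any(d_arr < 0):
            raise InvalidArgumentError("duration d must be >= 0")
        if np.any(d_arr > a_arr + 1e-12):
            raise InvalidArgumentError("duration d cannot exceed age a "
                                       "(onset cannot precede birth)")
        if self.duration_profile is not None:
            return self.duration_profile(d) * self.mortality_healthy(t, a)
        return self.mortality_diseased(t, a, d)


@dataclass(frozen=True)
class GeneralMortalityRates:
    """Rates given as (incidence, general mortality m, relative mortality R).

    This is the bundle typically available in practice: ``m`` from vital
    statistics or life tables, ``R = m1_star / m0`` from disease-specific
    surveys.  ``relative_mortality`` may be a constant or a function of
    ``(t, a)``.
    """

    incidence: RateFunction
    general_mortality: RateFunction
    relative_mortality: float | RateFunction = 1.0

    def __post_init__(self):
        if np.isscalar(self.relative_mortality) and not self.relative_mortality > 0:
            raise InvalidArgumentError("relative mortality R must be > 0")

    @property
    def incidence_min_age(self) -> float:
        return float(getattr(self.incidence, "min_age", 0.0))

    def relative_mortality_at(self, t, a):
        if callable(self.relative_mortality):
            return self.relative_mortality(t, a)
        shape = np.broadcast(np.asarray(t, float), np.asarray(a, float)).shape
        out = np.full(shape, float(self.relative_mortality))
        return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Quadrature: adaptive Romberg with a prescribed accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadratureSettings:
    """Accuracy control for the Romberg integrations.

    ``relative_tolerance`` is the target relative accuracy of every
    integral; the default 1e-8 makes the prevalence values stable to
    well beyond 7 printed decimals.  ``max_refinements`` bounds the
    number of grid halvings (2**max_refinements + 1 abscissae at most).
    """

    relative_tolerance: float = 1e-8
    absolute_tolerance: float = 1e-12
    max_refinements: int = 22

    def __post_init__(self):
        if not (self.relative_tolerance > 0 and self.absolute_tolerance > 0):
            raise InvalidArgumentError("tolerances must be > 0")
        if self.max_refinements < 4:
            raise InvalidArgumentError("max_refinements must be >= 4")


DEFAULT_QUADRATURE = QuadratureSettings()


def romberg(f, lo: float, hi: float,
            settings: QuadratureSettings = DEFAULT_QUADRATURE) -> float:
    """Integrate the vectorised function ``f`` over ``[lo, hi]``.

    Classic Romberg scheme: trapezoidal sums on successively halved
    grids, accelerated by Richardson extrapolation, stopped when two
    successive diagonal entries agree to the prescribed tolerance.

    Raises
    ------
    NumericalError
        If the tolerance is not met within ``max_refinements`` halvings;
        the error carries the last diagonal value as ``estimate``.
    """
    lo = float(lo)
    hi = float(hi)
    if not math.isfinite(lo) or not math.isfinite(hi) or hi < lo:
        raise InvalidArgumentError(f"invalid integration interval [{lo}, {hi}]")
    if hi == lo:
        return 0.0
    span = hi - lo
    ends = np.broadcast_to(np.asarray(f(np.array([lo, hi])), dtype=float), (2,))
    row = [span * 0.5 * float(ends[0] + ends[1])]
    for k in range(1, settings.max_refinements + 1):
        n_new = 2 ** (k - 1)
        x = lo + span * (2.0 * np.arange(n_new) + 1.0) / (2.0 ** k)
        fx = np.broadcast_to(np.asarray(f(x), dtype=float), x.shape)
        trap = 0.5 * row[0] + (span / 2.0 ** k) * float(np.sum(fx))
        new_row = [trap]
        for j in range(1, k + 1):
            factor = 4.0 ** j
            new_row.append(new_row[j - 1]
                           + (new_row[j - 1] - row[j - 1]) / (factor - 1.0))
        if k >= 4:
            err = abs(new_row[k] - row[k - 1])
            if err <= settings.absolute_tolerance \
                    + settings.relative_tolerance * abs(new_row[k]):
                return new_row[k]
        row = new_row
    raise NumericalError(
        f"Romberg quadrature on [{lo}, {hi}] did not converge within "
        f"{settings.max_refinements} refinements", estimate=row[-1])


def _romberg_split(f, points: Sequence[float],
                   settings: QuadratureSettings) -> float:
    """Romberg over consecutive panels; split at known kinks of f."""
    return sum(romberg(f, p0, p1, settings)
               for p0, p1 in zip(points, points[1:]) if p1 > p0)


class _CohortCache:
    """Cumulative hazards of one birth cohort on a shared fine grid.

    For the cohort with ``t - a = cohort`` the cache holds, on a dyadic
    age grid over ``[a_lo, a_hi]``,

    * ``cum_total(y)`` = integral over [a_lo, y] of (m0 + i) along the
      cohort diagonal (the exponent of the healthy survival), and
    * ``cum_m0(y)``    = the same for m0 alone (the building block of
      the duration hazard when m1 = R(d) * m0).

    Grids are refined by doubling until the cumulative values are
    stable to the quadrature tolerance, then once more for margin;
    evaluation in between nodes uses monotone (PCHIP) interpolation.
    """

    def __init__(self, rates: IllnessDeathRates, cohort: float,
                 a_lo: float, a_hi: float,
                 settings: QuadratureSettings = DEFAULT_QUADRATURE):
        self.cohort = cohort
        self.a_lo = a_lo
        self.a_hi = a_hi
        if a_hi <= a_lo:
            raise InvalidArgumentError("cohort cache needs a_hi > a_lo")
        n = 128
        x = np.linspace(a_lo, a_hi, n + 1)
        f_m0, f_tot = self._hazards(rates, x)
        cum_m0 = cumulative_simpson(f_m0, x=x, initial=0.0)
        cum_tot = cumulative_simpson(f_tot, x=x, initial=0.0)
        for _ in range(settings.max_refinements):
            n *= 2
            x2 = np.linspace(a_lo, a_hi, n + 1)
            f_m0, f_tot = self._hazards(rates, x2)
            cum_m0_2 = cumulative_simpson(f_m0, x=x2, initial=0.0)
            cum_tot_2 = cumulative_simpson(f_tot, x=x2, initial=0.0)
            err = max(float(np.max(np.abs(cum_m0_2[::2] - cum_m0))),
                      float(np.max(np.abs(cum_tot_2[::2] - cum_tot))))
            scale = max(1.0, float(cum_tot_2[-1]))
            x, cum_m0, cum_tot = x2, cum_m0_2, cum_tot_2
            if err <= settings.absolute_tolerance \
                    + settings.relative_tolerance * scale:
                # one safety doubling beyond apparent convergence
                n *= 2
                x = np.linspace(a_lo, a_hi, n + 1)
                f_m0, f_tot = self._hazards(rates, x)
                cum_m0 = cumulative_simpson(f_m0, x=x, initial=0.0)
                cum_tot = cumulative_simpson(f_tot, x=x, initial=0.0)
                break
        else:  # pragma: no cover - requires pathological rates
            raise NumericalError("cumulative-hazard cache did not converge",
                                 estimate=float(cum_tot[-1]))
        self.cum_m0 = PchipInterpolator(x, cum_m0)
        self.cum_total = PchipInterpolator(x, cum_tot)

    def _hazards(self, rates: IllnessDeathRates, ages: np.ndarray):
        times = self.cohort + ages
        m0 = np.asarray(rates.mortality_healthy(times, ages), dtype=float)
        inc = np.asarray(rates.incidence(times, ages), dtype=float)
        return m0, m0 + inc


# ---------------------------------------------------------------------------
# Forward model: survival, duration hazards, m1*, Keiding prevalence
# ---------------------------------------------------------------------------


def cumulative_duration_hazard(rates: IllnessDeathRates, t: float, a: float,
                               d: float,
                               settings: QuadratureSettings = DEFAULT_QUADRATURE
                               ) -> float:
    """Cumulative mortality hazard accrued over a disease spell.

    Integrates ``m1`` backwards along the life line of a person aged
    ``a`` at time ``t`` whose disease began ``d`` years ago:
    ``M1(t, a, d) = integral over [0, d] of m1(t-d+s, a-d+s, s) ds``.
    """
    _require_finite("cumulative_duration_hazard arguments", t, a, d)
    if d < 0 or d > a:
        raise InvalidArgumentError(f"need 0 <= d <= a, got d={d}, a={a}")
    if d == 0:
        return 0.0
    profile = rates.duration_profile
    if profile is not None:
        # m1 = R(s) m0: integrate m0 along the diagonal, piecewise in R
        def m0_diag(s):
            return rates.mortality_healthy(t - d + s, a - d + s)

        edges = [0.0] + [b for b in profile.breakpoints if 0.0 < b < d] + [d]
        return sum(float(profile(0.5 * (lo + hi))) * romberg(m0_diag, lo, hi, settings)
                   for lo, hi in zip(edges, edges[1:]))

    def m1_diag(s):
        return rates.m1(t - d + s, a - d + s, s)

    return romberg(m1_diag, 0.0, d, settings)


def survival_healthy(rates: IllnessDeathRates, t: float, a: float,
                     settings: QuadratureSettings = DEFAULT_QUADRATURE) -> float:
    """Probability of still being alive and healthy at age ``a``.

    The birth-cohort size is normalised to 1, so this is
    ``exp(-integral over [0, a] of (m0 + i) along the cohort diagonal)``.
    """
    _require_finite("survival_healthy arguments", t, a)
    if a < 0:
        raise InvalidArgumentError("age a must be >= 0")
    if a == 0:
        return 1.0

    def outflow(tau):
        return (rates.mortality_healthy(t - a + tau, tau)
                + rates.incidence(t - a + tau, tau))

    return math.exp(-romberg(outflow, 0.0, a, settings))


def _duration_hazard_on_nodes(rates: IllnessDeathRates, cache: _CohortCache,
                              t: float, a: float, deltas: np.ndarray,
                              settings: QuadratureSettings) -> np.ndarray:
    """Vectorised M1(t, a, delta) for the onset offsets ``deltas``.

    In the multiplicative representation the integral telescopes into
    differences of the cached cumulative m0 hazard, split at the
    duration-profile breakpoints; an arbitrary m1 falls back to one
    Romberg integral per node.
    """
    deltas = np.asarray(deltas, dtype=float)
    profile = rates.duration_profile
    if profile is None:
        return np.array([cumulative_duration_hazard(rates, t, a, dd, settings)
                         for dd in np.atleast_1d(deltas)]).reshape(deltas.shape)
    onset_age = a - deltas
    cum = cache.cum_m0
    if profile.is_constant:
        return profile.default_value * (cum(a) - cum(onset_age))
    total = np.zeros_like(deltas)
    prev_edge = 0.0
    for edge, value in zip(profile.breakpoints + (math.inf,),
                           profile.values + (profile.default_value,)):
        lo = np.minimum(deltas, prev_edge)
        hi = np.minimum(deltas, edge)
        seg = np.maximum(hi - lo, 0.0)
        active = seg > 0
        if np.any(active):
            upper = cum(onset_age[active] + hi[active])
            lower = cum(onset_age[active] + lo[active])
            total[active] += value * (upper - lower)
        prev_edge = edge
    return total


def _prevalence_parts(rates: IllnessDeathRates, t: float, a: float,
                      settings: QuadratureSettings):
    """Shared machinery of the Keiding prevalence ratio.

    Returns ``(diseased, healthy, cache, outer_breaks)`` where
    ``diseased`` is the onset-time integral (the numerator of the
    prevalence ratio) and ``healthy`` the surviving-healthy term, both
    normalised by the common survival up to the incidence onset age.
    That common factor -- including whatever m0 does below the onset
    age -- cancels in the ratio and is never evaluated.
    """
    a_min = rates.incidence_min_age
    span = a - a_min
    cache = _CohortCache(rates, t - a, a_min, a, settings)
    cum_total = cache.cum_total

    def integrand(delta):
        delta = np.asarray(delta, dtype=float)
        onset_age = a - delta
        m1_cum = _duration_hazard_on_nodes(rates, cache, t, a, delta, settings)
        return (np.asarray(rates.incidence(t - delta, onset_age), dtype=float)
                * np.exp(-(np.asarray(cum_total(onset_age), dtype=float) + m1_cum)))

    breaks = [0.0]
    if rates.duration_profile is not None and not rates.duration_profile.is_constant:
        breaks += [b for b in rates.duration_profile.breakpoints if 0.0 < b < span]
    breaks.append(span)
    diseased = _romberg_split(integrand, breaks, settings)
    healthy = math.exp(-float(cum_total(a)))
    return diseased, healthy, cache, (breaks, integrand)


def prevalence_keiding(rates: IllnessDeathRates, t: float, a: float,
                       settings: QuadratureSettings = DEFAULT_QUADRATURE
                       ) -> float:
    """Age-specific prevalence from the rates via Keiding's formula.

    Evaluates the closed-form ratio of the diseased cohort integral to
    the total surviving cohort: every person diseased at ``(t, a)``
    contracted the disease some ``delta`` years ago, survived healthy to
    the onset, and then survived ``delta`` years of diseased mortality;
    the integral over ``delta`` is compared with the people who are
    still healthy.  The birth-cohort size and all survival before the
    incidence onset age cancel in the ratio.
    """
    _require_finite("prevalence arguments", t, a)
    if a < 0:
        raise InvalidArgumentError("age a must be >= 0")
    if a <= rates.incidence_min_age:
        return 0.0
    diseased, healthy, _, _ = _prevalence_parts(rates, t, a, settings)
    if healthy == 0.0:
        raise NumericalError(
            f"healthy survival underflowed at (t={t}, a={a}); prevalence "
            "is numerically indistinguishable from 1", estimate=1.0)
    return diseased / (healthy + diseased)


def m1_star(rates: IllnessDeathRates, t: float, a: float,
            settings: QuadratureSettings = DEFAULT_QUADRATURE) -> float:
    """Duration-averaged mortality of the diseased at ``(t, a)``.

    The mean of ``m1(t, a, d)`` over the duration distribution of the
    prevalent cases, i.e. weighted by the diseased density ``C(t, a, d)``
    from the closed-form cohort solution; 0 when the diseased pool is
    empty (at or below the incidence onset age).
    """
    _require_finite("m1_star arguments", t, a)
    if a < 0:
        raise InvalidArgumentError("age a must be >= 0")
    if a <= rates.incidence_min_age:
        return 0.0
    _, _, cache, (breaks, weight) = _prevalence_parts(rates, t, a, settings)
    denom = _romberg_split(weight, breaks, settings)
    if denom <= 0.0:
        return 0.0
    profile = rates.duration_profile
    if profile is not None:
        # R is constant inside each split panel; evaluate at the midpoint
        # to avoid the right-continuity jump at the panel's upper edge
        m0_now = float(rates.mortality_healthy(t, a))
        numer = sum(float(profile(0.5 * (p0 + p1)))
                    * m0_now * romberg(weight, p0, p1, settings)
                    for p0, p1 in zip(breaks, breaks[1:]) if p1 > p0)
    else:
        def weighted(delta):
            return np.asarray(rates.m1(t, a, delta), dtype=float) * weight(delta)

        numer = _romberg_split(weighted, breaks, settings)
    return numer / denom


@dataclass(frozen=True)
class PrevalenceSurface:
    """Age-specific prevalence on a (time x age) grid."""

    time_points: np.ndarray
    ages: np.ndarray
    values: np.ndarray  # shape (len(time_points), len(ages))

    def __post_init__(self):
        tp = np.atleast_1d(np.asarray(self.time_points, dtype=float))
        ages = np.atleast_1d(np.asarray(self.ages, dtype=float))
        vals = np.asarray(self.values, dtype=float).reshape(len(tp), len(ages))
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", vals)
        if np.any(np.diff(ages) <= 0):
            raise InvalidArgumentError("ages must be strictly ascending")
        if np.any(vals < 0) or np.any(vals >= 1):
            raise InvalidArgumentError("prevalence values must lie in [0, 1)")

    def to_frame(self) -> pd.DataFrame:
        t_col = np.repeat(self.time_points, len(self.ages))
        a_col = np.tile(self.ages, len(self.time_points))
        return pd.DataFrame({"time": t_col, "age": a_col,
                             "prevalence": self.values.ravel()})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def prevalence_surface(rates: IllnessDeathRates, time_points, ages,
                       settings: QuadratureSettings = DEFAULT_QUADRATURE
                       ) -> PrevalenceSurface:
    """Evaluate :func:`prevalence_keiding` on a (time x age) grid."""
    time_points = np.atleast_1d(np.asarray(time_points, dtype=float))
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(np.diff(ages) <= 0):
        raise InvalidArgumentError("ages must be strictly ascending")
    values = np.empty((len(time_points), len(ages)))
    for j, t in enumerate(time_points):
        for k, a in enumerate(ages):
            try:
                values[j, k] = prevalence_keiding(rates, t, a, settings)
            except NumericalError as exc:
                raise NumericalError(
                    f"prevalence failed at (t={t}, a={a}): {exc}",
                    estimate=exc.estimate) from exc
    return PrevalenceSurface(time_points, ages, values)


# ---------------------------------------------------------------------------
# Characteristic PDE solvers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacteristicSolverSettings:
    """Runge-Kutta discretisation of the characteristic ODE.

    ``step_size`` is the target age step; the actual step divides the
    integration span exactly.  ``start_age`` is where the prevalence is
    pinned to 0 (defaults to the incidence onset age: nobody can be
    diseased before the disease can start).
    """

    step_size: float = 0.05
    start_age: float | None = None

    def __post_init__(self):
        if not self.step_size > 0:
            raise InvalidArgumentError("step_size must be > 0")


DEFAULT_SOLVER = CharacteristicSolverSettings()

# excursions of p outside [0,1] larger than this are treated as failures
_PDE_CLIP_TOLERANCE = 1e-9


def _integrate_characteristic(rhs, a0: float, a1: float, h_target: float,
                              record: bool = False):
    """Fixed-step classic RK4 for p' = rhs(a, p) with p(a0) = 0."""
    n = max(1, int(math.ceil((a1 - a0) / h_target - 1e-12)))
    h = (a1 - a0) / n
    p = 0.0
    ages = [a0]
    path = [0.0]
    for k in range(n):
        x = a0 + k * h
        k1 = rhs(x, p)
        k2 = rhs(x + 0.5 * h, p + 0.5 * h * k1)
        k3 = rhs(x + 0.5 * h, p + 0.5 * h * k2)
        k4 = rhs(x + h, p + h * k3)
        p = p + h * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        if p < -_PDE_CLIP_TOLERANCE or p > 1.0 + _PDE_CLIP_TOLERANCE:
            raise NumericalError(
                f"prevalence left [0, 1] at age {x + h:.3f} (p={p!r})",
                estimate=p)
        p = min(max(p, 0.0), 1.0)
        if record:
            ages.append(x + h)
            path.append(p)
    if record:
        return np.asarray(ages), np.asarray(path)
    return p


def _m1_star_along_characteristic(rates: IllnessDeathRates, cohort: float,
                                  a0: float, a1: float,
                                  quadrature: QuadratureSettings):
    """Interpolant of m1_star(cohort + a, a) for a duration-dependent m1.

    m1_star is smooth but expensive (a nested quadrature per point); it
    is precomputed on a 1-year age grid along the characteristic and
    monotone-interpolated to the Runge-Kutta nodes.  At the start age
    the diseased pool is empty and the duration-zero limit applies.
    """
    n = max(4, int(math.ceil(a1 - a0)))
    grid = np.linspace(a0, a1, n + 1)
    vals = np.empty_like(grid)
    for j, g in enumerate(grid):
        if g <= a0:
            vals[j] = float(rates.m1(cohort + g, max(g, 1e-9), 0.0)) if g > 0 \
                else 0.0
        else:
            vals[j] = m1_star(rates, cohort + g, g, quadrature)
    return PchipInterpolator(grid, vals)


def solve_prevalence_pde(rates: IllnessDeathRates, t: float, a: float,
                         settings: CharacteristicSolverSettings = DEFAULT_SOLVER,
                         quadrature: QuadratureSettings = DEFAULT_QUADRATURE,
                         return_path: bool = False):
    """Prevalence from the transport equation along the characteristic.

    Integrates ``dp/da = (1-p) * (i - p*(m1_star - m0))`` from
    ``(t - a + a0, a0)`` with ``p = 0`` up to ``(t, a)``.  For a
    duration-independent diseased mortality ``m1_star = m1`` exactly;
    otherwise ``m1_star`` is sourced from the closed-form cohort
    solution (see :func:`m1_star`) on a grid along the characteristic.

    With ``return_path=True`` the full trajectory ``(ages, p)`` is
    returned instead of the endpoint value.
    """
    _require_finite("solve_prevalence_pde arguments", t, a)
    a0 = settings.start_age if settings.start_age is not None \
        else rates.incidence_min_age
    if a < a0:
        raise InvalidArgumentError(f"age a={a} below start_age {a0}")
    cohort = t - a
    if a == a0:
        return (np.array([a0]), np.array([0.0])) if return_path else 0.0
    if rates.duration_independent:
        ratio = rates.duration_profile.default_value

        def excess(tt, aa):
            return (ratio - 1.0) * rates.mortality_healthy(tt, aa)
    else:
        ms = _m1_star_along_characteristic(rates, cohort, a0, a, quadrature)

        def excess(tt, aa):
            return ms(aa) - rates.mortality_healthy(tt, aa)

    def rhs(aa, p):
        tt = cohort + aa
        inc = float(rates.incidence(tt, aa))
        return (1.0 - p) * (inc - p * float(excess(tt, aa)))

    return _integrate_characteristic(rhs, a0, a, settings.step_size,
                                     record=return_path)


def attributable_fraction(p: float, relative_mortality: float) -> float:
    """Share of overall mortality attributable to the disease.

    ``p*(R-1) / (p*(R-1) + 1)`` -- the population attributable fraction
    for prevalence ``p`` and mortality rate ratio ``R``.
    """
    _require_finite("attributable_fraction arguments", p, relative_mortality)
    if not 0.0 <= p <= 1.0:
        raise InvalidArgumentError("prevalence p must be in [0, 1]")
    if not relative_mortality > 0:
        raise InvalidArgumentError("relative mortality R must be > 0")
    excess = p * (relative_mortality - 1.0)
    return excess / (excess + 1.0)


def solve_prevalence_general(rates: GeneralMortalityRates, t: float, a: float,
                             settings: CharacteristicSolverSettings = DEFAULT_SOLVER,
                             return_path: bool = False):
    """Prevalence when only general mortality and relative mortality are known.

    Integrates ``dp/da = (1-p) * (i - m * PAF(p, R))`` along the
    characteristic, where ``m`` is the whole-population mortality and
    ``PAF`` the population attributable fraction.  This is the form
    usable with vital statistics (m) plus a mortality rate ratio (R),
    when the state-specific mortalities m0 and m1 are unavailable.
    """
    _require_finite("solve_prevalence_general arguments", t, a)
    a0 = settings.start_age if settings.start_age is not None \
        else rates.incidence_min_age
    if a < a0:
        raise InvalidArgumentError(f"age a={a} below start_age {a0}")
    cohort = t - a
    if a == a0:
        return (np.array([a0]), np.array([0.0])) if return_path else 0.0

    def rhs(aa, p):
        tt = cohort + aa
        inc = float(rates.incidence(tt, aa))
        m = float(rates.general_mortality(tt, aa))
        r = float(rates.relative_mortality_at(tt, aa))
        paf = attributable_fraction(min(max(p, 0.0), 1.0), r)
        return (1.0 - p) * (inc - m * paf)

    return _integrate_characteristic(rhs, a0, a, settings.step_size,
                                     record=return_path)


# ---------------------------------------------------------------------------
# Incidence from two cross-sectional prevalence surveys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossSection:
    """One cross-sectional survey: age-specific prevalence at one time.

    ``survey_time`` is on whatever time scale the caller uses
    consistently (the experiment drivers use calendar years).
    """

    survey_time: float
    ages: np.ndarray
    prevalence: np.ndarray

    def __post_init__(self):
        ages = np.atleast_1d(np.asarray(self.ages, dtype=float))
        prev = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "prevalence", prev)
        _require_finite("CrossSection", self.survey_time, ages, prev)
        if len(ages) != len(prev):
            raise InvalidArgumentError("ages and prevalence must have equal length")
        if np.any(np.diff(ages) <= 0):
            raise InvalidArgumentError("ages must be strictly increasing")
        if np.any(prev < 0) or np.any(prev >= 1):
            raise InvalidArgumentError("prevalence must lie in [0, 1)")

    @classmethod
    def from_csv(cls, path, survey_time: float) -> "CrossSection":
        df = pd.read_csv(path)
        missing = {"age", "prevalence"} - set(df.columns)
        if missing:
            raise InvalidArgumentError(
                f"cross-section CSV {path} lacks columns: {sorted(missing)}")
        return cls(float(survey_time), df["age"].to_numpy(),
                   df["prevalence"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "prevalence": self.prevalence}) \
            .to_csv(path, index=False)


_AGE_MATCH_TOLERANCE = 1e-8


def _prevalence_at(cs: CrossSection, age: float, interpolate: bool) -> float:
    hits = np.flatnonzero(np.abs(cs.ages - age) <= _AGE_MATCH_TOLERANCE)
    if hits.size:
        return float(cs.prevalence[hits[0]])
    if interpolate and cs.ages[0] <= age <= cs.ages[-1] and len(cs.ages) >= 2:
        return float(PchipInterpolator(cs.ages, cs.prevalence)(age))
    raise MissingSupportError(
        f"age {age} is not on the grid of the survey at time {cs.survey_time}")


def _lag(cs0: CrossSection, cs1: CrossSection) -> float:
    delta = cs1.survey_time - cs0.survey_time
    if not delta > 0:
        raise InvalidArgumentError(
            f"surveys must be ordered in time with a positive lag, got "
            f"{cs0.survey_time} and {cs1.survey_time}")
    return delta


def midpoint_prevalence(cs0: CrossSection, cs1: CrossSection, a: float,
                        interpolate: bool = False) -> float:
    """Prevalence at the survey midpoint, age ``a``, by linear averaging.

    The two surveys straddle the target point along the cohort
    characteristic, so the mean of ``p(t0, a - lag/2)`` and
    ``p(t0 + lag, a + lag/2)`` is second-order accurate (exact whenever
    p is affine in (t, a)).
    """
    delta = _lag(cs0, cs1)
    p0 = _prevalence_at(cs0, a - delta / 2.0, interpolate)
    p1 = _prevalence_at(cs1, a + delta / 2.0, interpolate)
    return 0.5 * (p0 + p1)


def directional_derivative(cs0: CrossSection, cs1: CrossSection, a: float,
                           interpolate: bool = False) -> float:
    """Finite-difference estimate of (d/dt + d/da) p at the midpoint."""
    delta = _lag(cs0, cs1)
    p0 = _prevalence_at(cs0, a - delta / 2.0, interpolate)
    p1 = _prevalence_at(cs1, a + delta / 2.0, interpolate)
    return (p1 - p0) / delta


@dataclass(frozen=True)
class IncidenceEstimate:
    """Output of the two-cross-section incidence estimator.

    Estimates refer to the survey midpoint ``midpoint_time``;
    ``negative_incidence`` flags ages where the point estimate came out
    below zero (a symptom of inconsistent inputs -- reported, not
    clamped).
    """

    midpoint_time: float
    ages: np.ndarray
    incidence: np.ndarray
    midpoint_prevalence: np.ndarray
    directional_derivative: np.ndarray
    negative_incidence: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages,
            "incidence": self.incidence,
            "midpoint_prevalence": self.midpoint_prevalence,
            "directional_derivative": self.directional_derivative,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def estimate_incidence(cs0: CrossSection, cs1: CrossSection,
                       m0_fn: RateFunction, m1_star_fn: RateFunction,
                       ages=None, interpolate: bool = False
                       ) -> IncidenceEstimate:
    """Estimate age-specific incidence from two prevalence surveys.

    Solving the prevalence transport equation for the incidence gives

        i = (d/dt + d/da) p / (1 - p) + p * (m1_star - m0),

    evaluated at the survey midpoint with the directional derivative and
    the midpoint prevalence approximated from the two surveys.  The
    mortality functions must be evaluable at the midpoint time on the
    same time scale as the survey times.

    By default the output ages are all ``a`` for which both
    ``a - lag/2`` and ``a + lag/2`` lie on the respective survey grids;
    with ``interpolate=True`` off-grid ages are filled by monotone
    interpolation instead of raising.
    """
    delta = _lag(cs0, cs1)
    t_mid = cs0.survey_time + delta / 2.0
    if ages is None:
        ages = np.array([x + delta / 2.0 for x in cs0.ages
                         if np.any(np.abs(cs1.ages - (x + delta))
                                   <= _AGE_MATCH_TOLERANCE)])
        if ages.size == 0:
            raise MissingSupportError(
                "no age has both a-lag/2 and a+lag/2 on the survey grids")
    else:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))

    p_mid = np.empty_like(ages)
    deriv = np.empty_like(ages)
    inc = np.empty_like(ages)
    for j, a in enumerate(ages):
        p0 = _prevalence_at(cs0, a - delta / 2.0, interpolate)
        p1 = _prevalence_at(cs1, a + delta / 2.0, interpolate)
        pm = 0.5 * (p0 + p1)
        if pm >= 1.0:
            raise ZeroDivisionError(
                f"midpoint prevalence is 1 at age {a}; the incidence "
                "equation divides by 1 - p")
        dd = (p1 - p0) / delta
        excess = float(m1_star_fn(t_mid, a)) - float(m0_fn(t_mid, a))
        p_mid[j] = pm
        deriv[j] = dd
        inc[j] = dd / (1.0 - pm) + pm * excess
    negative = inc < 0
    if np.any(negative):
        warnings.warn(
            f"negative incidence estimates at ages "
            f"{ages[negative].tolist()}; inputs may be inconsistent "
            "(estimates are reported unclamped)", RuntimeWarning,
            stacklevel=2)
    return IncidenceEstimate(t_mid, ages, inc, p_mid, deriv, negative)


def relative_error(estimate, truth):
    """Signed percent deviation ``100 * (estimate - truth) / truth``."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.any(truth == 0):
        raise InvalidArgumentError("relative error is undefined for truth == 0")
    out = 100.0 * (estimate - truth) / truth
    return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Dementia simulation study and experiment drivers
# ---------------------------------------------------------------------------

# Rate constants of the dementia-in-German-males example: all-cause
# mortality of the non-demented approximated by a Gompertz hazard with a
# 1%-per-year secular decline since 1960, and a calendar-time-stable
# log-linear dementia incidence from age 50.
_DEMENTIA_TIME_ORIGIN = 1960.0
_DEMENTIA_M0 = dict(beta0=-9.0, beta_age=0.085, beta_time=-math.log(1.01))
_DEMENTIA_INCIDENCE = dict(beta0=-12.8, beta_age=0.11, beta_time=0.0, min_age=50.0)
_DEMENTIA_RELATIVE_MORTALITY = 2.63
# average relative mortality over years 1-4 after diagnosis; used above
# age 90, where few survive long enough for the years 1-6 average to apply
_DEMENTIA_RELATIVE_MORTALITY_OLDEST = 2.755


def dementia_rates(relative_mortality: float | DurationProfile | None = None
                   ) -> IllnessDeathRates:
    """The dementia-in-German-males model instance.

    ``relative_mortality`` may be a constant (default 2.63, the average
    mortality rate ratio of demented vs non-demented persons over the
    first six years after diagnosis in an English cohort) or a
    :class:`DurationProfile` for a duration-dependent excess mortality.
    """
    if relative_mortality is None:
        relative_mortality = _DEMENTIA_RELATIVE_MORTALITY
    profile = relative_mortality if isinstance(relative_mortality, DurationProfile) \
        else DurationProfile.constant(float(relative_mortality))
    return IllnessDeathRates(
        incidence=ParametricRate(**_DEMENTIA_INCIDENCE),
        mortality_healthy=ParametricRate(**_DEMENTIA_M0),
        duration_profile=profile,
        time_origin=_DEMENTIA_TIME_ORIGIN,
    )


def dementia_config_path() -> Path:
    """Path of the shipped dementia rate-configuration file."""
    from importlib.resources import files

    return Path(str(files("previnc").joinpath("data/dementia_germany.yaml")))


@dataclass(frozen=True)
class ExperimentSpec:
    """A simulated two-survey study design.

    The forward model generates the age course of the prevalence at the
    two survey years (mimicking two cross-sectional studies), and the
    estimator is then run with the *assumed* relative mortality -- which
    may deliberately differ from the one that generated the data, to
    study misspecification of the excess mortality.

    ``assumed_relative_mortality`` is a constant or a function of age
    (e.g. a higher ratio above age 90, reflecting that the recently
    diagnosed dominate the oldest diseased).
    """

    rates: IllnessDeathRates = field(default_factory=dementia_rates)
    survey_years: tuple[float, float] = (2010.0, 2015.0)
    ages: np.ndarray = field(
        default_factory=lambda: np.arange(60.0, 100.0 + 1e-9, 2.5))
    method: str = "keiding"
    quadrature: QuadratureSettings = DEFAULT_QUADRATURE
    solver: CharacteristicSolverSettings = DEFAULT_SOLVER
    assumed_relative_mortality: float | Callable[[float], float] = \
        _DEMENTIA_RELATIVE_MORTALITY

    def __post_init__(self):
        ages = np.atleast_1d(np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "ages", ages)
        y0, y1 = self.survey_years
        if not y1 > y0:
            raise InvalidArgumentError("survey years must be distinct and ordered")
        spacing = np.diff(ages)
        if len(ages) < 2 or np.any(spacing <= 0) \
                or not np.allclose(spacing, spacing[0]):
            raise InvalidArgumentError("age grid must ascend with constant spacing")
        if self.method not in ("keiding", "pde"):
            raise InvalidArgumentError("method must be 'keiding' or 'pde'")

    @property
    def lag(self) -> float:
        return self.survey_years[1] - self.survey_years[0]

    @property
    def midpoint_year(self) -> float:
        return self.survey_years[0] + self.lag / 2.0


def _calendar_m0(spec: ExperimentSpec) -> RateFunction:
    origin = spec.rates.time_origin

    def m0(year, a):
        return spec.rates.mortality_healthy(np.asarray(year, float) - origin, a)

    return m0


def _calendar_assumed_m1_star(spec: ExperimentSpec) -> RateFunction:
    m0 = _calendar_m0(spec)
    assumed = spec.assumed_relative_mortality
    if callable(assumed):
        def ms(year, a):
            return np.asarray(assumed(a), dtype=float)[()] * m0(year, a) \
                if np.ndim(a) == 0 else np.asarray(assumed(a), dtype=float) * m0(year, a)
    else:
        ratio = float(assumed)

        def ms(year, a):
            return ratio * m0(year, a)

    return ms


def generate_cross_sections(spec: ExperimentSpec
                            ) -> tuple[CrossSection, CrossSection]:
    """Forward-model the two surveys of an experiment.

    Each survey's age-specific prevalence is computed point by point by
    the Keiding integral formula (or, with ``method='pde'``, the
    characteristic solver) at the survey year.
    """
    origin = spec.rates.time_origin
    sections = []
    for year in spec.survey_years:
        t = year - origin
        if spec.method == "keiding":
            values = np.array([prevalence_keiding(spec.rates, t, a, spec.quadrature)
                               for a in spec.ages])
        else:
            values = np.array([solve_prevalence_pde(spec.rates, t, a,
                                                    spec.solver, spec.quadrature)
                               for a in spec.ages])
        logger.info("survey %s: %d ages, prevalence range [%.3g, %.3g]",
                    year, len(spec.ages), values.min(), values.max())
        sections.append(CrossSection(year, spec.ages, values))
    return sections[0], sections[1]


@dataclass(frozen=True)
class ComparisonTable:
    """True vs estimated incidence, with signed percent errors."""

    ages: np.ndarray
    true_incidence: np.ndarray
    calculated_incidence: np.ndarray
    relative_error_pct: np.ndarray

    def __post_init__(self):
        n = len(np.atleast_1d(self.ages))
        for name in ("true_incidence", "calculated_incidence", "relative_error_pct"):
            if len(np.atleast_1d(getattr(self, name))) != n:
                raise InvalidArgumentError("table columns must have equal length")

    @property
    def max_abs_relative_error(self) -> float:
        return float(np.max(np.abs(self.relative_error_pct)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages,
            "true_incidence": self.true_incidence,
            "calculated_incidence": self.calculated_incidence,
            "relative_error_pct": self.relative_error_pct,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_recovery_study(spec: ExperimentSpec | None = None) -> ComparisonTable:
    """Simulate two surveys and check how well the estimator recovers i.

    The forward model generates the prevalence cross-sections, the
    two-survey estimator is applied with the spec's assumed excess
    mortality, and the estimates are compared with the incidence that
    actually generated the data.  With the default spec this is the
    dementia validation study: surveys in 2010 and 2015 on ages 60-100
    in steps of 2.5 years, constant relative mortality 2.63, yielding 15
    estimates at ages 62.5, ..., 97.5 with all errors below 2%.
    """
    if spec is None:
        spec = ExperimentSpec()
    cs0, cs1 = generate_cross_sections(spec)
    estimate = estimate_incidence(cs0, cs1, _calendar_m0(spec),
                                  _calendar_assumed_m1_star(spec))
    t_mid = spec.midpoint_year - spec.rates.time_origin
    truth = np.array([float(spec.rates.incidence(t_mid, a))
                      for a in estimate.ages])
    errors = relative_error(estimate.incidence, truth)
    logger.info("recovery study: %d ages, max |relative error| %.3f%%",
                len(estimate.ages), float(np.max(np.abs(errors))))
    return ComparisonTable(estimate.ages, truth, estimate.incidence, errors)


def run_duration_study(profile: DurationProfile,
                       assumed_relative_mortality: float | Callable[[float], float]
                       = _DEMENTIA_RELATIVE_MORTALITY,
                       spec: ExperimentSpec | None = None) -> ComparisonTable:
    """Recovery study with a duration-dependent diseased mortality.

    The surveys are generated with ``m1(t, a, d) = R(d) * m0(t, a)`` for
    the given duration profile, but the estimator is run with the
    (duration-free) assumed relative mortality -- quantifying the error
    induced by summarising a duration-dependent excess mortality with a
    single ratio, or with an age-piecewise one.
    """
    if spec is None:
        spec = ExperimentSpec()
    rates = dataclasses.replace(spec.rates, duration_profile=profile,
                                mortality_diseased=None)
    spec = dataclasses.replace(
        spec, rates=rates,
        assumed_relative_mortality=assumed_relative_mortality)
    return run_recovery_study(spec)


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------


def _parametric_from_config(block: dict, name: str) -> ParametricRate:
    if not isinstance(block, dict) or "beta0" not in block:
        raise InvalidArgumentError(f"config block '{name}' must map beta0/"
                                   "beta_age/beta_time/min_age")
    return ParametricRate(
        beta0=float(block["beta0"]),
        beta_age=float(block.get("beta_age", 0.0)),
        beta_time=float(block.get("beta_time", 0.0)),
        min_age=float(block.get("min_age", 0.0)),
    )


def _profile_from_config(block) -> DurationProfile:
    if isinstance(block, (int, float)):
        return DurationProfile.constant(float(block))
    if not isinstance(block, dict):
        raise InvalidArgumentError("relative_mortality must be a constant or a mapping")
    if "constant" in block:
        return DurationProfile.constant(float(block["constant"]))
    return DurationProfile(
        breakpoints=tuple(float(b) for b in block.get("breakpoints", ())),
        values=tuple(float(v) for v in block.get("values", ())),
        default_value=float(block.get("default", 1.0)),
    )


def load_rates(path) -> IllnessDeathRates:
    """Read an :class:`IllnessDeathRates` bundle from a YAML/JSON file.

    Expected blocks: ``incidence`` and ``mortality_healthy`` (each with
    ``beta0``, ``beta_age``, ``beta_time``, ``min_age``),
    ``relative_mortality`` (``{constant: x}`` or ``{breakpoints: [...],
    values: [...], default: x}``) and ``time_origin``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise InvalidArgumentError(f"rate config {path} is not a mapping")
    for key in ("incidence", "mortality_healthy", "relative_mortality"):
        if key not in data:
            raise InvalidArgumentError(f"rate config {path} lacks block '{key}'")
    rates = IllnessDeathRates(
        incidence=_parametric_from_config(data["incidence"], "incidence"),
        mortality_healthy=_parametric_from_config(
            data["mortality_healthy"], "mortality_healthy"),
        duration_profile=_profile_from_config(data["relative_mortality"]),
        time_origin=float(data.get("time_origin", 1960.0)),
    )
    logger.info("loaded rates from %s (time origin %s)", path, rates.time_origin)
    return rates
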