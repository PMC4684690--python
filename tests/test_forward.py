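"""Forward model: quadrature, survival, duration hazards, m1*, prevalence."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, simpson

import previnc as pv


def _quad_survival_exponent(rates, t, a):
    """Independent scipy.quad oracle for the healthy outflow integral."""
    val, _ = quad(lambda tau: float(rates.mortality_healthy(t - a + tau, tau))
                  + float(rates.incidence(t - a + tau, tau)),
                  0.0, a, limit=400,
                  points=[rates.incidence_min_age] if a > rates.incidence_min_age else None)
    return val


class TestRomberg:
    def test_smooth_integrals(self):
        assert pv.romberg(np.exp, 0.0, 1.0) == pytest.approx(math.e - 1.0, rel=1e-10)
        assert pv.romberg(lambda x: x ** 3, 0.0, 2.0) == pytest.approx(4.0, rel=1e-10)
        assert pv.romberg(np.cos, 0.0, 0.0) == 0.0

    def test_nonconvergence_carries_estimate(self):
        settings = pv.QuadratureSettings(relative_tolerance=1e-14,
                                         absolute_tolerance=1e-16,
                                         max_refinements=4)
        with pytest.raises(pv.NumericalError) as err:
            pv.romberg(lambda x: np.cos(40.0 * x) ** 2, 0.0, 3.0, settings)
        assert err.value.estimate is not None and np.isfinite(err.value.estimate)

    def test_settings_validation(self):
        with pytest.raises(pv.InvalidArgumentError):
            pv.QuadratureSettings(relative_tolerance=0.0)
        with pytest.raises(pv.InvalidArgumentError):
            pv.QuadratureSettings(max_refinements=3)


class TestCumulativeDurationHazard:
    def test_empty_spell_and_bounds(self, dementia):
        assert pv.cumulative_duration_hazard(dementia, 50.0, 80.0, 0.0) == 0.0
        with pytest.raises(pv.InvalidArgumentError):
            pv.cumulative_duration_hazard(dementia, 50.0, 80.0, -1.0)
        with pytest.raises(pv.InvalidArgumentError):
            pv.cumulative_duration_hazard(dementia, 50.0, 80.0, 81.0)

    def test_constant_m1_closed_form(self):
        rates = pv.IllnessDeathRates(
            pv.zero_rate(), pv.constant_rate(0.01),
            mortality_diseased=lambda t, a, d: np.full(np.shape(d), 0.3)[()]
            if np.ndim(d) else 0.3)
        assert pv.cumulative_duration_hazard(rates, 10.0, 40.0, 7.0) \
            == pytest.approx(0.3 * 7.0, rel=1e-10)

    def test_matches_fine_simpson_oracle(self, dementia):
        t, a, d = 50.0, 80.0, 10.0
        tau = np.linspace(0.0, d, 10001)
        vals = 2.63 * dementia.mortality_healthy(t - d + tau, a - d + tau)
        oracle = simpson(vals, x=tau)
        assert pv.cumulative_duration_hazard(dementia, t, a, d) \
            == pytest.approx(oracle, rel=1e-8)

    def test_nondecreasing_in_duration(self, dementia):
        values = [pv.cumulative_duration_hazard(dementia, 50.0, 90.0, d)
                  for d in (0.0, 1.0, 5.0, 20.0, 40.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_step_profile_splits_at_breakpoints(self):
        profile = pv.DurationProfile((2.0,), (4.0,), 2.0)
        rates = pv.dementia_rates(profile)
        t, a, d = 50.0, 80.0, 5.0
        oracle = 0.0
        for lo, hi, ratio in [(0.0, 2.0, 4.0), (2.0, d, 2.0)]:
            tau = np.linspace(lo, hi, 10001)
            oracle += ratio * simpson(
                rates.mortality_healthy(t - d + tau, a - d + tau), x=tau)
        assert pv.cumulative_duration_hazard(rates, t, a, d) \
            == pytest.approx(oracle, rel=1e-6)


class TestSurvivalHealthy:
    def test_no_outflow_gives_one(self):
        rates = pv.IllnessDeathRates(
            pv.zero_rate(), pv.zero_rate(),
            duration_profile=pv.DurationProfile.constant(1.0))
        assert pv.survival_healthy(rates, 0.0, 0.0) == 1.0
        assert pv.survival_healthy(rates, 10.0, 70.0) == pytest.approx(1.0)

    def test_constant_outflow_closed_form(self):
        rates = pv.IllnessDeathRates(
            pv.constant_rate(0.02), pv.constant_rate(0.01),
            duration_profile=pv.DurationProfile.constant(1.0))
        assert pv.survival_healthy(rates, 30.0, 40.0) \
            == pytest.approx(math.exp(-0.03 * 40.0), rel=1e-10)

    def test_dementia_against_quad_oracle(self, dementia):
        t, a = 50.0, 80.0
        oracle = math.exp(-_quad_survival_exponent(dementia, t, a))
        assert pv.survival_healthy(dementia, t, a) == pytest.approx(oracle, rel=1e-8)

    def test_negative_age_rejected(self, dementia):
        with pytest.raises(pv.InvalidArgumentError):
            pv.survival_healthy(dementia, 0.0, -1.0)


class TestM1Star:
    def test_constant_ratio_reduces_to_m1(self, dementia):
        for t, a in [(50.0, 70.0), (55.0, 95.0)]:
            expected = 2.63 * dementia.mortality_healthy(t, a)
            assert pv.m1_star(dementia, t, a) == pytest.approx(expected, rel=1e-8)

    def test_empty_diseased_pool_gives_zero(self, dementia):
        assert pv.m1_star(dementia, 50.0, 50.0) == 0.0
        assert pv.m1_star(dementia, 50.0, 30.0) == 0.0

    def test_bounded_by_m1_range(self):
        profile = pv.DurationProfile((1.0, 4.0), (4.0, 2.5), 1.8)
        rates = pv.dementia_rates(profile)
        t, a = 52.5, 85.0
        ms = pv.m1_star(rates, t, a)
        m0 = rates.mortality_healthy(t, a)
        assert 1.8 * m0 < ms < 4.0 * m0

    def test_two_level_profile_against_trapezoid_oracle(self):
        """Brute-force the duration-weighted mean on a 200k-point grid."""
        profile = pv.DurationProfile((1.0, 4.0), (4.0, 2.5), 1.8)
        rates = pv.dementia_rates(profile)
        t, a, a_min = 52.5, 85.0, 50.0
        n = 200_000
        d = np.linspace(0.0, a - a_min, n + 1)
        y = a - d
        tau = np.linspace(a_min, a, n + 1)
        tot = rates.mortality_healthy(t - a + tau, tau) + rates.incidence(t - a + tau, tau)
        cum_tot = np.concatenate([[0.0], np.cumsum((tot[1:] + tot[:-1]) / 2 * np.diff(tau))])
        m0d = rates.mortality_healthy(t - a + tau, tau)
        cum_m0 = np.concatenate([[0.0], np.cumsum((m0d[1:] + m0d[:-1]) / 2 * np.diff(tau))])
        m1_cum = np.zeros_like(d)
        prev = 0.0
        for bp, val in zip((1.0, 4.0, np.inf), (4.0, 2.5, 1.8)):
            lo = np.minimum(d, prev)
            hi = np.minimum(d, bp)
            m1_cum += val * (np.interp(y + hi, tau, cum_m0)
                             - np.interp(y + lo, tau, cum_m0))
            prev = bp
        weight = rates.incidence(t - d, y) * np.exp(-(np.interp(y, tau, cum_tot) + m1_cum))
        m1_now = rates.duration_profile(d) * rates.mortality_healthy(t, a)
        oracle = np.trapezoid(m1_now * weight, d) / np.trapezoid(weight, d)
        assert pv.m1_star(rates, t, a) == pytest.approx(oracle, rel=1e-4)


class TestPrevalenceKeiding:
    def test_zero_incidence_gives_zero_prevalence(self):
        rates = pv.IllnessDeathRates(
            pv.zero_rate(), pv.constant_rate(0.01),
            duration_profile=pv.DurationProfile.constant(2.0))
        for t, a in [(0.0, 0.0), (10.0, 40.0), (50.0, 95.0)]:
            assert pv.prevalence_keiding(rates, t, a) == 0.0

    def test_constant_rates_closed_form(self):
        # with m1 = m0 the prevalence obeys dp/da = (1 - p) i
        rates = pv.IllnessDeathRates(
            pv.constant_rate(0.02), pv.constant_rate(0.01),
            duration_profile=pv.DurationProfile.constant(1.0))
        for a in (5.0, 30.0, 60.0):
            assert pv.prevalence_keiding(rates, 30.0, a) \
                == pytest.approx(1.0 - math.exp(-0.02 * a), rel=1e-9)

    def test_zero_at_and_below_incidence_onset(self, dementia):
        assert pv.prevalence_keiding(dementia, 50.0, 50.0) == 0.0
        assert pv.prevalence_keiding(dementia, 50.0, 20.0) == 0.0

    def test_tolerance_self_consistency(self, dementia):
        p_coarse = pv.prevalence_keiding(
            dementia, 50.0, 85.0, pv.QuadratureSettings(relative_tolerance=1e-6))
        p_fine = pv.prevalence_keiding(
            dementia, 50.0, 85.0, pv.QuadratureSettings(relative_tolerance=5e-7))
        assert abs(p_coarse - p_fine) < 1e-6

    def test_survival_below_onset_age_cancels(self, dementia):
        """Extra hazard confined below the incidence onset age leaves p unchanged."""

        class Bumped:
            min_age = 0.0

            def __init__(self, base):
                self.base = base

            def __call__(self, t, a):
                a = np.asarray(a, float)
                out = self.base(t, a) + np.where(a < 50.0, 0.05, 0.0)
                return out[()] if out.ndim == 0 else out

        bumped = pv.IllnessDeathRates(
            dementia.incidence, Bumped(dementia.mortality_healthy),
            duration_profile=dementia.duration_profile)
        for t, a in [(50.0, 70.0), (55.0, 100.0)]:
            assert pv.prevalence_keiding(bumped, t, a) \
                == pv.prevalence_keiding(dementia, t, a)

    def test_saturated_prevalence_raises_instead_of_returning_one(self):
        rates = pv.IllnessDeathRates(
            pv.constant_rate(0.01), pv.constant_rate(10.0),
            duration_profile=pv.DurationProfile.constant(0.001))
        with pytest.raises(pv.NumericalError):
            pv.prevalence_keiding(rates, 90.0, 90.0)


class TestPrevalenceSurface:
    def test_dementia_grid_invariants(self, dementia):
        ages = np.arange(50.0, 100.01, 10.0)
        surface = pv.prevalence_surface(dementia, [50.0, 55.0], ages)
        assert surface.values.shape == (2, len(ages))
        assert np.all(surface.values >= 0) and np.all(surface.values < 1)
        assert np.all(surface.values[:, 0] == 0.0)  # age 50: onset age
        assert np.all(np.diff(surface.values, axis=1) >= 0)  # increasing in age

    def test_single_point_matches_pointwise_evaluation(self, dementia):
        surface = pv.prevalence_surface(dementia, 50.0, 80.0)
        assert surface.values[0, 0] == pv.prevalence_keiding(dementia, 50.0, 80.0)

    def test_csv_round_trip(self, dementia, tmp_path):
        surface = pv.prevalence_surface(dementia, [50.0], [60.0, 70.0])
        out = tmp_path / "surface.csv"
        surface.to_csv(out)
        text = out.read_text().splitlines()
        assert text[0] == "time,age,prevalence"
        assert len(text) == 3

    def test_invalid_grid_rejected(self, dementia):
        with pytest.raises(pv.InvalidArgumentError):
            pv.prevalence_surface(dementia, [50.0], [70.0, 60.0])
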