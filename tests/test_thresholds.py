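"""Closed-form threshold quantities: B, S*, S~e, R1, R2, phi*, floors."""

import math
from dataclasses import replace

import numpy as np
import pytest

from shidr import (PulseSchedule, basic_reproduction_R1, basic_reproduction_R2,
                   compute_thresholds, critical_pulse_rate_phi_star,
                   depletion_level_B, permanence_floor, rumor_free_solution,
                   vaccinated_fixed_point_S_star,
                   PHI_STAR_NOT_NEEDED, PHI_STAR_ROOT, PHI_STAR_UNATTAINABLE)
from shidr.scenarios import random_valid_parameters


def exact_R1(params, schedule, digits=30):
    """Independent extended-precision oracle via sympy rationals."""
    from sympy import Rational, exp
    a = Rational(str(max(params.alpha1, params.alpha2)))
    rho = Rational(str(min(params.rho1, params.rho2)))
    th, g1, g2, mu = (Rational(str(v)) for v in
                      (params.theta, params.gamma1, params.gamma2, params.mu))
    sig = min(th * g1 + mu, g2 + mu)
    pi, phi, T, tau = (Rational(str(v)) for v in
                       (params.pi, schedule.phi, schedule.T, schedule.tau))
    E = exp(-mu * T)
    B = pi * (1 - E) / (mu * (1 - (1 - phi) * E))
    return float((a * exp(-mu * tau) * B / ((1 + rho * B) * sig)).evalf(digits))


def exact_R2(params, schedule, digits=30):
    from sympy import Rational, exp
    a = Rational(str(min(params.alpha1, params.alpha2)))
    rho = Rational(str(max(params.rho1, params.rho2)))
    th, g1, g2, mu = (Rational(str(v)) for v in
                      (params.theta, params.gamma1, params.gamma2, params.mu))
    sig = max(th * g1 + mu, g2 + mu)
    pi, phi, T, tau = (Rational(str(v)) for v in
                       (params.pi, schedule.phi, schedule.T, schedule.tau))
    E = exp(-mu * T)
    s_star = pi * (1 - phi) * (1 - E) / (mu * (1 - (1 - phi) * E))
    return float(((a * exp(-mu * tau) / sig - rho) * s_star).evalf(digits))


class TestDepletionLevel:
    def test_no_pulsing_gives_carrying_level(self, scheme1):
        sched = PulseSchedule(phi=0.0, T=3.7, tau=0.0)
        pm = scheme1.params.pi / scheme1.params.mu
        assert depletion_level_B(scheme1.params, sched) == pytest.approx(pm, rel=1e-14)

    def test_benchmark_value_matches_extended_precision(self, scheme1, base_schedule):
        from sympy import Rational, exp
        E = exp(Rational(-1, 50))  # e^{-mu T} with mu=0.01, T=2
        exact = (1 - E) / (1 - Rational(4, 5) * E)
        assert depletion_level_B(scheme1.params, base_schedule) == \
            pytest.approx(float(exact.evalf(30)), rel=1e-14)

    def test_long_period_limit_is_carrying_level(self, scheme1):
        sched = PulseSchedule(phi=0.6, T=5000.0, tau=0.0)
        pm = scheme1.params.pi / scheme1.params.mu
        assert depletion_level_B(scheme1.params, sched) == pytest.approx(pm, rel=1e-9)

    def test_bounded_by_carrying_level(self):
        for seed in range(200):
            params, sched = random_valid_parameters(seed)
            b = depletion_level_B(params, sched)
            assert 0.0 < b <= params.pi / params.mu + 1e-12


class TestFixedPoint:
    def test_is_one_minus_phi_times_B(self):
        for seed in range(200):
            params, sched = random_valid_parameters(seed)
            assert vaccinated_fixed_point_S_star(params, sched) == pytest.approx(
                (1 - sched.phi) * depletion_level_B(params, sched), rel=1e-13)

    def test_benchmark_value(self, scheme2, base_schedule):
        assert vaccinated_fixed_point_S_star(scheme2.params, base_schedule) == \
            pytest.approx(0.420315726697, rel=1e-10)

    def test_unique_fixed_point_of_pulse_period_map(self):
        """S* is the fixed point of x -> (1-phi)(pi/mu + (x-pi/mu)e^{-mu T})."""
        for seed in range(100):
            params, sched = random_valid_parameters(seed)
            pm = params.pi / params.mu
            s = vaccinated_fixed_point_S_star(params, sched)
            mapped = (1 - sched.phi) * (pm + (s - pm) * math.exp(-params.mu * sched.T))
            assert mapped == pytest.approx(s, rel=1e-12, abs=1e-14)


class TestRumorFreeSolution:
    def test_right_limit_at_pulse_instants_is_S_star(self, scheme1, base_schedule):
        s_star = vaccinated_fixed_point_S_star(scheme1.params, base_schedule)
        for n in range(4):
            got = rumor_free_solution(n * base_schedule.T, scheme1.params, base_schedule)
            assert got == pytest.approx(s_star, rel=1e-12)

    def test_periodic(self, scheme2, base_schedule):
        t = 0.73
        a = rumor_free_solution(t, scheme2.params, base_schedule)
        b = rumor_free_solution(t + 3 * base_schedule.T, scheme2.params, base_schedule)
        assert a == pytest.approx(b, rel=1e-12)

    def test_no_pulsing_gives_constant_carrying_level(self, scheme3):
        sched = PulseSchedule(phi=0.0, T=2.0, tau=0.0)
        pm = scheme3.params.pi / scheme3.params.mu
        for t in (0.0, 0.5, 1.99, 7.3):
            assert rumor_free_solution(t, scheme3.params, sched) == \
                pytest.approx(pm, rel=1e-12)


class TestReproductionNumbers:
    @pytest.mark.parametrize("phi, expected", [(0.2, 0.741772937242),
                                               (0.5, 0.314324633109)])
    def test_R1_extinction_regime_below_one(self, scheme1, phi, expected):
        sched = PulseSchedule(phi=phi, T=2.0, tau=1.0)
        r1 = basic_reproduction_R1(scheme1.params, sched)
        assert r1 == pytest.approx(expected, rel=1e-10)
        assert r1 == pytest.approx(exact_R1(scheme1.params, sched), rel=1e-13)
        assert r1 < 1

    @pytest.mark.parametrize("phi, expected", [(0.2, 1.67769007000),
                                               (0.3, 1.18643469045)])
    def test_R2_persistent_regime_above_one(self, scheme2, phi, expected):
        sched = PulseSchedule(phi=phi, T=2.0, tau=1.0)
        r2 = basic_reproduction_R2(scheme2.params, sched)
        assert r2 == pytest.approx(expected, rel=1e-10)
        assert r2 == pytest.approx(exact_R2(scheme2.params, sched), rel=1e-13)
        assert r2 > 1

    def test_R1_collapses_without_delay_pulse_saturation(self):
        from shidr import ModelParameters
        p = ModelParameters(pi=0.3, mu=0.2, alpha1=0.7, alpha2=0.4, rho1=0.0,
                            rho2=0.0, gamma1=0.5, gamma2=0.9, theta=0.5, k=0.5)
        sched = PulseSchedule(phi=0.0, T=1.0, tau=0.0)
        sigma = min(p.theta * p.gamma1 + p.mu, p.gamma2 + p.mu)
        expected = max(p.alpha1, p.alpha2) * p.pi / (p.mu * sigma)
        assert basic_reproduction_R1(p, sched) == pytest.approx(expected, rel=1e-13)

    def test_R2_collapses_without_delay_and_saturation(self, scheme2):
        p = replace(scheme2.params, rho1=0.0, rho2=0.0)
        sched = PulseSchedule(phi=0.2, T=2.0, tau=0.0)
        sigma = max(p.theta * p.gamma1 + p.mu, p.gamma2 + p.mu)
        expected = min(p.alpha1, p.alpha2) * \
            vaccinated_fixed_point_S_star(p, sched) / sigma
        assert basic_reproduction_R2(p, sched) == pytest.approx(expected, rel=1e-13)

    def test_R2_sign_agrees_with_incidence_form(self):
        """sign(R2 - 1) = sign(a' e^{-mu tau} S*/((1+rho' S*) sigma') - 1)."""
        for seed in range(1000):
            params, sched = random_valid_parameters(seed)
            r2 = basic_reproduction_R2(params, sched)
            s = vaccinated_fixed_point_S_star(params, sched)
            a = min(params.alpha1, params.alpha2)
            rho = max(params.rho1, params.rho2)
            sigma = max(params.theta * params.gamma1 + params.mu,
                        params.gamma2 + params.mu)
            inc_form = a * math.exp(-params.mu * sched.tau) * s / ((1 + rho * s) * sigma)
            assert (r2 > 1) == (inc_form > 1)

    def test_monotone_nonincreasing_in_phi_and_rho(self, scheme1):
        base = PulseSchedule(phi=0.0, T=2.0, tau=1.0)
        r1_lo = basic_reproduction_R1(scheme1.params, base)
        r2_lo = basic_reproduction_R2(scheme1.params, base)
        harder = replace(scheme1.params, rho1=0.4, rho2=0.4)
        for params, sched in [(scheme1.params, PulseSchedule(phi=0.4, T=2.0, tau=1.0)),
                              (harder, base)]:
            assert basic_reproduction_R1(params, sched) <= r1_lo
            assert basic_reproduction_R2(params, sched) <= r2_lo


class TestCriticalPulseRate:
    def test_root_brings_R1_to_one(self, scheme1):
        phi, status = critical_pulse_rate_phi_star(scheme1.params, T=2.0, tau=1.0)
        assert status == PHI_STAR_ROOT
        assert 0.0 < phi < 0.2  # R1(0.2) < 1 already
        r1 = basic_reproduction_R1(scheme1.params,
                                   PulseSchedule(phi=phi, T=2.0, tau=1.0))
        assert abs(r1 - 1.0) <= 1e-10

    def test_matches_closed_form(self, scheme1):
        """phi* = (e^{mu T} - 1)((pi/mu)(alpha e^{-mu tau}/sigma - rho) - 1),
        derived by inverting R1(phi) = 1; the root-solve is authoritative."""
        p = scheme1.params
        alpha = max(p.alpha1, p.alpha2)
        rho = min(p.rho1, p.rho2)
        sigma = min(p.theta * p.gamma1 + p.mu, p.gamma2 + p.mu)
        G = (p.pi / p.mu) * (alpha * math.exp(-p.mu * 1.0) / sigma - rho)
        closed = (math.exp(p.mu * 2.0) - 1.0) * (G - 1.0)
        phi, _ = critical_pulse_rate_phi_star(p, T=2.0, tau=1.0)
        assert phi == pytest.approx(closed, abs=1e-9)

    def test_agrees_with_fine_grid_scan(self, scheme1):
        phi_star, _ = critical_pulse_rate_phi_star(scheme1.params, T=2.0, tau=1.0)
        grid = np.linspace(0.0, 0.999, 20001)
        r1 = np.array([basic_reproduction_R1(scheme1.params,
                                             PulseSchedule(phi=v, T=2.0, tau=1.0))
                       for v in grid])
        crossing = grid[np.searchsorted(-(r1 - 1.0), 0.0)]
        assert abs(phi_star - crossing) < 1e-4

    def test_above_the_root_extinction_threshold_holds(self, scheme1):
        phi_star, _ = critical_pulse_rate_phi_star(scheme1.params, T=2.0, tau=1.0)
        for phi in np.linspace(phi_star + 1e-6, 0.99, 25):
            assert basic_reproduction_R1(
                scheme1.params, PulseSchedule(phi=float(phi), T=2.0, tau=1.0)) < 1.0

    def test_flag_when_no_vaccination_needed(self, scheme3):
        # strong media exposure and a long delay: R1(0) < 1 already
        phi, status = critical_pulse_rate_phi_star(scheme3.params, T=2.0, tau=4.0)
        assert status == PHI_STAR_NOT_NEEDED and phi == 0.0

    def test_flag_when_pulsing_alone_insufficient(self, scheme1):
        hot = replace(scheme1.params, alpha1=50.0, alpha2=50.0, rho1=0.0, rho2=0.0)
        phi, status = critical_pulse_rate_phi_star(hot, T=2.0, tau=0.0)
        assert status == PHI_STAR_UNATTAINABLE and math.isnan(phi)


class TestPermanenceFloor:
    def test_undefined_when_no_permanence_guarantee(self, scheme1, base_schedule):
        assert permanence_floor(scheme1.params, base_schedule) == (None, None)

    def test_no_delay_gives_half_F_star(self, scheme2):
        sched = PulseSchedule(phi=0.2, T=2.0, tau=0.0)
        f_star, p = permanence_floor(scheme2.params, sched)
        assert p == pytest.approx(f_star / 2, rel=1e-14)

    def test_benchmark_value_matches_hand_arithmetic(self, scheme2, base_schedule):
        r2 = basic_reproduction_R2(scheme2.params, base_schedule)
        f_expected = 0.1 / 0.9 * (r2 - 1.0)   # (mu/alpha)(R2 - 1), alpha = 0.9
        sigma_p = 0.18                         # max(0.5*0.09+0.1, 0.08+0.1)
        f_star, p = permanence_floor(scheme2.params, base_schedule)
        assert f_star == pytest.approx(f_expected, rel=1e-12)
        assert p == pytest.approx(min(f_expected / 2,
                                      f_expected * math.exp(-sigma_p * 1.0)),
                                  rel=1e-12)
        assert p > 0


class TestReport:
    def test_extremal_ingredients_and_serialization(self, scheme2, base_schedule):
        rep = compute_thresholds(scheme2.params, base_schedule)
        assert (rep.alpha_max, rep.alpha_min) == (0.9, 0.8)
        assert (rep.rho_min, rep.rho_max) == (0.02, 0.03)
        assert rep.sigma_min == pytest.approx(0.145)
        assert rep.sigma_max == pytest.approx(0.18)
        assert rep.S_star == pytest.approx((1 - 0.2) * rep.B, rel=1e-13)
        import json
        d = json.loads(rep.to_json())
        assert set(d) >= {"R1", "R2", "phi_star", "B", "S_star", "F_star", "P_floor"}
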