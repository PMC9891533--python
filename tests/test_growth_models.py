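"""Growth-model solvers against closed-form and root-finding oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from spheromap.growth_models import (
    GompertzParams,
    GreenspanParams,
    LogisticParams,
    RadialDeathParams,
    RichardsParams,
    TimeGrid,
    crowding_function,
    greenspan_inner_radii,
    solve_bounded_gompertz,
    solve_greenspan,
    solve_logistic,
    solve_radial_death,
    solve_richards,
)

T = np.arange(0.0, 22.0)


def logistic_oracle(lam, rmax, r0, t):
    return rmax / (1.0 + (rmax / r0 - 1.0) * np.exp(-lam * np.asarray(t) / 3.0))


class TestLogistic:
    def test_matches_closed_form(self):
        traj = solve_logistic(LogisticParams(1.21, 316.0), 10.0, T)
        np.testing.assert_allclose(traj.radius, logistic_oracle(1.21, 316.0, 10.0, T), rtol=1e-12)

    def test_matches_ode_integration(self):
        lam, rmax, r0 = 1.21, 316.0, 10.0
        sol = solve_ivp(
            lambda _t, y: [(lam / 3) * y[0] * (1 - y[0] / rmax)],
            (0, 21), [r0], t_eval=T, rtol=1e-10, atol=1e-12,
        )
        traj = solve_logistic(LogisticParams(lam, rmax), r0, T)
        np.testing.assert_allclose(traj.radius, sol.y[0], rtol=1e-7)

    @pytest.mark.parametrize(
        "params, r0, expect",
        [
            (LogisticParams(1.21, 316.0), 316.0, 316.0),  # fixed point
            (LogisticParams(0.0, 316.0), 10.0, 10.0),  # no growth
        ],
    )
    def test_degenerate_solutions_are_constant(self, params, r0, expect):
        traj = solve_logistic(params, r0, T)
        np.testing.assert_allclose(traj.radius, expect, rtol=1e-12)

    @pytest.mark.parametrize("bad_r0", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_initial_radius_rejected(self, bad_r0):
        with pytest.raises(ValueError):
            solve_logistic(LogisticParams(1.0, 300.0), bad_r0, T)


class TestBoundedGompertz:
    def test_exponential_below_switch_radius(self):
        p = GompertzParams(1.0, 300.0)
        t_star = 3.0 * math.log(p.Rmax / (math.e * 10.0))
        t = np.linspace(0.0, t_star * 0.999, 15)
        traj = solve_bounded_gompertz(p, 10.0, t)
        np.testing.assert_allclose(traj.radius, 10.0 * np.exp(t / 3.0), rtol=1e-12)

    def test_continuity_across_switch(self):
        p = GompertzParams(1.3, 280.0)
        t_star = (3.0 / p.lam) * math.log(p.Rmax / (math.e * 10.0))
        eps = 1e-7
        t = np.array([t_star - eps, t_star, t_star + eps])
        r = solve_bounded_gompertz(p, 10.0, t).radius
        # value continuity and slope continuity at the switch
        assert abs(r[1] - p.Rmax / math.e) < 1e-6
        slope_left = (r[1] - r[0]) / eps
        slope_right = (r[2] - r[1]) / eps
        assert slope_left == pytest.approx(slope_right, rel=1e-5)

    def test_fixed_point_at_rmax(self):
        traj = solve_bounded_gompertz(GompertzParams(1.0, 300.0), 300.0, T)
        np.testing.assert_allclose(traj.radius, 300.0, rtol=1e-12)

    def test_matches_ode_integration(self):
        p = GompertzParams(1.0, 300.0)
        sol = solve_ivp(
            lambda _t, y: [(p.lam / 3) * y[0] * min(math.log(p.Rmax / y[0]), 1.0)],
            (0, 21), [10.0], t_eval=T, rtol=1e-10, atol=1e-12,
        )
        traj = solve_bounded_gompertz(p, 10.0, T)
        np.testing.assert_allclose(traj.radius, sol.y[0], rtol=1e-6)


class TestRichards:
    def test_beta_one_recovers_logistic(self):
        rich = solve_richards(RichardsParams(1.21, 316.0, 1.0), 10.0, T)
        logi = solve_logistic(LogisticParams(1.21, 316.0), 10.0, T)
        assert np.max(np.abs(rich.radius - logi.radius)) < 1e-8 * 316.0

    def test_small_beta_approaches_gompertz_limit(self):
        # standard (unbounded) Gompertz closed form as the beta -> 0 oracle:
        # since 1 - u^beta ~ beta * log(1/u), the Richards model at growth
        # rate lam/beta converges to the Gompertz model at rate lam
        lam, rmax, r0 = 1.0, 300.0, 10.0
        gomp = rmax * np.exp(math.log(r0 / rmax) * np.exp(-lam * T / 3.0))
        errs = []
        for beta in (1e-1, 1e-2, 1e-3):
            rich = solve_richards(RichardsParams(lam / beta, rmax, beta), r0, T)
            errs.append(np.max(np.abs(rich.radius - gomp)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[-1] < 1e-2 * rmax

    def test_fixed_point_at_rmax(self):
        traj = solve_richards(RichardsParams(1.0, 300.0, 2.5), 300.0, T)
        np.testing.assert_allclose(traj.radius, 300.0, rtol=1e-12)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            RichardsParams(1.0, 300.0, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.1, 5.0),
        rmax=st.floats(50.0, 2000.0),
        beta=st.floats(0.05, 5.0),
    )
    def test_solution_bounded_and_monotone(self, lam, rmax, beta):
        traj = solve_richards(RichardsParams(lam, rmax, beta), 10.0, T)
        if rmax > 10.0:
            assert np.all(traj.radius <= rmax * (1 + 1e-9))
            assert np.all(np.diff(traj.radius) >= -1e-9)


class TestRadialDeath:
    def test_exponential_while_below_rim(self):
        p = RadialDeathParams(1.0, 1.0, 150.0)
        t_cross = 3.0 * math.log(150.0 / 10.0)
        t = np.linspace(0.0, t_cross * 0.99, 12)
        traj = solve_radial_death(p, 10.0, t)
        np.testing.assert_allclose(traj.radius, 10.0 * np.exp(t / 3.0), rtol=1e-12)

    def test_steady_state_matches_root_oracle(self):
        # at lam = zeta, (R*-Rd)^3/R*^3 = 1/2  =>  R* = Rd / (1 - 2^(-1/3))
        p = RadialDeathParams(1.0, 1.0, 150.0)
        r_star = 150.0 / (1.0 - 2.0 ** (-1.0 / 3.0))
        traj = solve_radial_death(p, 10.0, np.array([0.0, 400.0, 500.0]))
        assert traj.radius[-1] == pytest.approx(r_star, rel=1e-3)
        assert abs(traj.radius[-1] - traj.radius[-2]) < 1e-2 * r_star

    def test_no_loss_is_monotone(self):
        traj = solve_radial_death(RadialDeathParams(1.0, 0.0, 80.0), 10.0, T)
        assert np.all(np.diff(traj.radius) >= 0.0)


class TestGreenspanInnerRadii:
    def test_phase_one_has_no_inner_structure(self):
        assert greenspan_inner_radii(100.0, GreenspanParams(0.8, 150.0, 1.0, 1.0)) == (
            0.0, 0.0, 1,
        )

    def test_phase_two_closed_form(self):
        ri, rn, phase = greenspan_inner_radii(130.0, GreenspanParams(0.8, 150.0, 1.0, 1.0))
        assert phase == 2
        assert rn == 0.0
        assert ri == pytest.approx(math.sqrt(130.0**2 - 120.0**2), rel=1e-12)

    def test_phase_three_roots_satisfy_both_constraints(self):
        p = GreenspanParams(0.8, 150.0, 1.0, 1.0)
        for R in (160.0, 200.0, 320.0, 500.0):
            ri, rn, phase = greenspan_inner_radii(R, p)
            assert phase == 3
            assert 0.0 < rn < ri < R
            cubic = R**3 - p.Rd**2 * R - 3 * R * rn**2 + 2 * rn**3
            quart = (
                (p.Q * p.Rd) ** 2 * R * ri + R * ri**3 + 2 * R * rn**3
                - R**3 * ri - 2 * ri * rn**3
            )
            assert abs(cubic) < 1e-10 * R**3
            assert abs(quart) < 1e-10 * R**4

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        q=st.floats(0.2, 0.95),
        rd=st.floats(50.0, 400.0),
        R=st.floats(5.0, 1500.0),
    )
    def test_phase_ordering_invariant(self, q, rd, R):
        p = GreenspanParams(q, rd, 1.0, 1.0)
        ri, rn, phase = greenspan_inner_radii(R, p)
        assert 0.0 <= rn <= ri <= R + 1e-9
        if rn > 0:
            assert R >= rd
        if ri > 0:
            assert R >= q * rd - 1e-9


class TestGreenspanSolve:
    def test_phase_one_exact_exponential(self):
        p = GreenspanParams(0.8, 150.0, 1.0, 1.0)
        t_cross = 3.0 * math.log(120.0 / 10.0)
        t = np.linspace(0.0, t_cross * 0.99, 10)
        traj = solve_greenspan(p, 10.0, t)
        np.testing.assert_allclose(traj.radius, 10.0 * np.exp(t / 3.0), rtol=1e-12)
        assert np.all(traj.necrotic_radius == 0.0)

    def test_inner_radii_reported_consistently(self, greenspan_traj):
        p = GreenspanParams(0.8, 150.0, 1.0, 1.0)
        for R, ri, rn in zip(
            greenspan_traj.radius,
            greenspan_traj.inner_radius,
            greenspan_traj.necrotic_radius,
        ):
            ri2, rn2, _ = greenspan_inner_radii(R, p)
            assert ri == pytest.approx(ri2, abs=1e-9)
            assert rn == pytest.approx(rn2, abs=1e-9)

    def test_rhs_continuous_across_phase_boundaries(self):
        # dense output straddling R = Q Rd and R = Rd: radius stays smooth
        p = GreenspanParams(0.8, 150.0, 1.0, 1.0)
        t = np.linspace(7.0, 9.0, 400)  # crosses both boundaries
        r = solve_greenspan(p, 10.0, t).radius
        slopes = np.diff(r) / np.diff(t)
        # second differences of the slope stay bounded (no kinks)
        assert np.max(np.abs(np.diff(slopes))) < 0.1

    def test_matches_brute_force_reintegration(self, greenspan_traj):
        p = GreenspanParams(0.8, 150.0, 1.0, 1.0)
        from spheromap.growth_models import _greenspan_rhs

        sol = solve_ivp(
            lambda _t, y: [_greenspan_rhs(y[0], p)],
            (0.0, 21.0), [10.0], t_eval=T, rtol=1e-11, atol=1e-13,
        )
        np.testing.assert_allclose(greenspan_traj.radius, sol.y[0], rtol=1e-6)


class TestCrowding:
    @pytest.mark.parametrize(
        "model_id, params, radius, expected",
        [
            ("logistic", LogisticParams(1.0, 300.0), 300.0, 0.0),
            ("logistic", LogisticParams(1.0, 300.0), 150.0, 0.5),
            ("gompertz", GompertzParams(1.0, 300.0), 300.0 / math.e / 2, 1.0),
            ("richards", RichardsParams(1.0, 300.0, 2.0), 300.0, 0.0),
            ("greenspan", GreenspanParams(0.8, 150.0, 1.0, 1.0), 100.0, 1.0),
            ("radial_death", RadialDeathParams(1.0, 1.0, 150.0), 100.0, 1.0),
        ],
    )
    def test_known_values(self, model_id, params, radius, expected):
        curve = crowding_function(model_id, params, [radius])
        assert curve.f[0] == pytest.approx(expected, abs=1e-12)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            crowding_function("nonesuch", LogisticParams(1.0, 300.0), [100.0])


class TestTimeGrid:
    @pytest.mark.parametrize(
        "times", [[1.0, 1.0, 2.0], [2.0, 1.0], [-1.0, 0.0], [np.nan, 1.0], []]
    )
    def test_invalid_grids_rejected(self, times):
        with pytest.raises(ValueError):
            TimeGrid(np.asarray(times, dtype=float))
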