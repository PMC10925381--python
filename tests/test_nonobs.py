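"""Non-observation ODE: fixed points, closed forms, jumps, convergence."""

import math

import numpy as np
import pytest

from phylofe import (BDMSParams, CSESchedule, prob_nonempty, prune,
                     simulate_full, solve_nonobservation)
from phylofe.nonobs import NumericalError
from phylofe.presets import single_type_model, stick_model

from conftest import random_model


def riccati_E(tau, lam, mu, rho):
    """Closed-form E(tau) for a constant-rate single-type birth-death model
    with present-day sampling rho (no serial sampling)."""
    tau = np.asarray(tau, dtype=float)
    if abs(lam - mu) < 1e-12:
        return 1.0 - rho / (1.0 + rho * lam * tau)
    m = mu / lam
    k0 = -rho / (1.0 - rho - m)
    k = k0 * np.exp((lam - mu) * tau)
    return (1.0 - m * k) / (1.0 - k)


class TestFixedPoints:
    def test_no_sampling_anywhere_keeps_E_at_one(self):
        theta = single_type_model(1.0, 0.5, rho=0.0, t_max=2.0)
        sol = solve_nonobservation(theta)
        taus = np.linspace(0, 2, 50)
        assert np.allclose(sol.E_at(0, taus), 1.0)
        assert prob_nonempty(theta, sol) == 0.0

    def test_stick_process_E_is_one_minus_rho(self):
        theta = stick_model(rho=0.3, t_max=2.0)
        sol = solve_nonobservation(theta)
        taus = np.linspace(0.01, 2, 50)
        assert np.allclose(sol.E_at(0, taus), 0.7, atol=1e-12)
        # minus side at the present is the post-sampling limit
        assert sol.E_at(0, 0.0, side="minus") == 1.0
        assert sol.E_at(0, 0.0, side="plus") == pytest.approx(0.7)

    def test_complete_sampling_no_death_gives_probability_one(self, yule):
        sol = solve_nonobservation(yule)
        assert prob_nonempty(yule, sol) == pytest.approx(1.0, abs=1e-12)


class TestClosedForm:
    @pytest.mark.parametrize("lam,mu,rho", [(1.0, 0.5, 0.3), (0.6, 0.9, 0.8),
                                            (1.0, 1.0, 0.1)])
    def test_matches_constant_rate_solution(self, lam, mu, rho):
        theta = single_type_model(lam, mu, rho=rho, t_max=4.0)
        sol = solve_nonobservation(theta)
        taus = np.linspace(0, 4.0, 201)
        expected = riccati_E(taus, lam, mu, rho)
        got = sol.E_at(0, taus, side="plus")
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_critical_nonempty_probability(self):
        """1 - E(t_max) = rho / (1 + rho lam t_max) at criticality."""
        theta = single_type_model(1.0, 1.0, rho=0.1, t_max=1.0)
        sol = solve_nonobservation(theta)
        assert prob_nonempty(theta, sol) == pytest.approx(1 / 11, abs=1e-9)

    def test_nonempty_matches_monte_carlo(self, rng):
        """1 - sum_a pi_a E_a(t_max) equals the fraction of full+prune
        replicates with at least one sampled lineage."""
        theta = single_type_model(1.0, 0.5, rho=0.3, t_max=1.5)
        sol = solve_nonobservation(theta)
        p = prob_nonempty(theta, sol)
        reps = 20_000
        hits = sum(
            not prune(simulate_full(theta, rng, validate=False)[0]).is_empty
            for _ in range(reps))
        se = math.sqrt(p * (1 - p) / reps)
        assert abs(hits / reps - p) < 3 * se


class TestCSEJumps:
    def test_jump_consistency_is_exact_as_stored(self):
        theta = BDMSParams(
            types=["A"], pi=[1.0], lam=[[0.8]], mu=[0.3], gamma=[[0.0]],
            psi=[0.2], r=[0.5],
            cse=CSESchedule(times=[0.0, 1.0], rho=[[0.4, 0.25]], q=[[0.0, 0.5]]),
            t_max=2.0)
        sol = solve_nonobservation(theta)
        for l, (e_minus, e_plus) in enumerate(sol.cse_limits):
            rho_l = theta.cse.rho[:, l]
            assert np.array_equal(e_plus, (1 - rho_l) * e_minus)
        # the stored interval endpoints carry the one-sided limits
        assert sol.E_at(0, 1.0, side="minus") == pytest.approx(
            float(sol.cse_limits[1][0][0]))
        assert sol.E_at(0, 1.0, side="plus") == pytest.approx(
            float(sol.cse_limits[1][1][0]))


class TestNumerics:
    def test_rk4_refinement_order(self):
        """Halving the step size reduces the closed-form discrepancy by about
        the solver's order (2^4 = 16)."""
        theta = single_type_model(1.0, 0.5, rho=0.3, t_max=2.0)
        errs = []
        for steps in (16, 32):
            sol = solve_nonobservation(theta, steps_per_unit=steps)
            iv = sol.intervals[0]
            expected = riccati_E(iv.grid, 1.0, 0.5, 0.3)
            errs.append(np.max(np.abs(iv.E[0] - expected)))
        assert 8 < errs[0] / errs[1] < 32

    def test_tolerance_check_passes_at_default_resolution(self):
        theta = single_type_model(1.0, 0.5, rho=0.3, t_max=2.0)
        solve_nonobservation(theta, tolerance=1e-8)

    def test_unmet_tolerance_reports_achieved_error(self):
        theta = single_type_model(1.0, 0.5, rho=0.3, t_max=2.0)
        with pytest.raises(NumericalError) as exc:
            solve_nonobservation(theta, steps_per_unit=5, tolerance=1e-16)
        assert exc.value.achieved > 1e-16

    def test_increasing_rho_never_increases_E(self, rng):
        """Monotone response: more sampling cannot make observation less
        likely, at any time and for any type."""
        for _ in range(5):
            theta = random_model(rng)
            sol_lo = solve_nonobservation(theta)
            boosted = BDMSParams(
                types=theta.types, pi=theta.pi, lam=theta.lam, mu=theta.mu,
                gamma=theta.gamma, psi=theta.psi, r=theta.r,
                cse=CSESchedule(theta.cse.times,
                                np.clip(theta.cse.rho + 0.2, 0, 1),
                                theta.cse.q),
                t_max=theta.t_max)
            sol_hi = solve_nonobservation(boosted)
            taus = np.linspace(0, theta.t_max, 101)[1:]
            for a in range(theta.d):
                assert np.all(sol_hi.E_at(a, taus, side="plus")
                              <= sol_lo.E_at(a, taus, side="plus") + 1e-9)
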