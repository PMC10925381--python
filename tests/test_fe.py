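"""Forward-equivalent map and simulator: fixed points, invariants, biases,
the projection property, and Monte-Carlo distributional equivalence."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from phylofe import (BDMSParams, CSESchedule, count_leaf_nodes, fe_map,
                     prob_nonempty, prune, simulate_full,
                     simulate_reconstructed, solve_nonobservation)
from phylofe.fe import FEInfeasibleError, clear_fe_cache
from phylofe.presets import single_type_model, stick_model

from conftest import max_width, random_model


@pytest.fixture(autouse=True)
def _fresh_cache():
    clear_fe_cache()
    yield
    clear_fe_cache()


class TestFEMap:
    def test_identity_when_everything_is_observed(self, yule):
        """mu = psi = 0 and complete present sampling: E = 0, so F is the
        identity on every rate and on pi."""
        sol = solve_nonobservation(yule)
        fe = fe_map(yule, sol)
        taus = np.linspace(0, 1, 33)
        assert np.allclose(fe.pi, yule.pi)
        assert np.allclose(fe.lam[0][0].value_at(taus),
                           yule.lam[0][0].value_at(taus), atol=1e-12)
        assert np.allclose(fe.cse.rho, 1.0)

    def test_present_day_sampling_is_always_complete(self, rng):
        """rho^FE_{a,0} = 1 for every type of every model with positive
        non-emptiness probability, and mu^FE is identically zero."""
        for _ in range(8):
            theta = random_model(rng)
            sol = solve_nonobservation(theta)
            if prob_nonempty(theta, sol) == 0.0:
                continue
            fe = fe_map(theta, sol)
            assert np.allclose(fe.cse.rho[:, 0], 1.0, atol=1e-12)
            taus = np.linspace(0, theta.t_max, 17)
            for a in range(theta.d):
                assert np.all(np.asarray(fe.mu[a].value_at(taus)) == 0.0)

    def test_fig2_relative_birth_rate_exceeds_four(self, fig2_model):
        """With rho = 0.01, the transformed Fit/Unfit birth-rate ratio stays
        above the population value of 4 at every positive time."""
        sol = solve_nonobservation(fig2_model)
        fe = fe_map(fig2_model, sol)
        taus = sol.grid_all()
        taus = taus[taus >= 0.05]
        ratio = (np.asarray(fe.lam[0][0].value_at(taus))
                 / np.asarray(fe.lam[1][1].value_at(taus)))
        assert ratio.min() >= 4.0

    def test_mutation_bias_toward_observable_types(self, fig2_model):
        """E_a > E_b inflates gamma^FE_{a,b} above gamma_{a,b} (mutations
        toward better-observed types are enhanced); here Unfit -> Fit."""
        sol = solve_nonobservation(fig2_model)
        fe = fe_map(fig2_model, sol)
        taus = sol.grid_all()
        taus = taus[taus > 0.01]
        E_fit = sol.E_at(0, taus, side="plus")
        E_unfit = sol.E_at(1, taus, side="plus")
        assert np.all(E_unfit > E_fit)
        gamma_fe = np.asarray(fe.gamma[1][0].value_at(taus))
        assert np.all(gamma_fe > 0.5)

    def test_projection_property(self, rng):
        """F(F(theta)) = F(theta): solving the ODE under the transformed
        model gives E = 0, so a second application changes nothing."""
        for _ in range(5):
            theta = random_model(rng, max_types=2)
            sol = solve_nonobservation(theta)
            if prob_nonempty(theta, sol) < 1e-3:
                continue
            fe = fe_map(theta, sol)
            sol2 = solve_nonobservation(fe)
            assert max(abs(sol2.E_at(a, t, side="plus"))
                       for a in range(theta.d)
                       for t in np.linspace(0, theta.t_max, 64)) < 1e-6
            fe2 = fe_map(fe, sol2)
            taus = np.linspace(0, theta.t_max, 64)
            assert np.allclose(fe2.pi, fe.pi, atol=1e-6)
            for a in range(theta.d):
                for b in range(theta.d):
                    assert np.max(np.abs(
                        np.asarray(fe2.lam[a][b].value_at(taus))
                        - np.asarray(fe.lam[a][b].value_at(taus)))) < 1e-6
                    assert np.max(np.abs(
                        np.asarray(fe2.gamma[a][b].value_at(taus))
                        - np.asarray(fe.gamma[a][b].value_at(taus)))) < 1e-6
                assert np.max(np.abs(
                    np.asarray(fe2.psi[a].value_at(taus))
                    - np.asarray(fe.psi[a].value_at(taus)))) < 1e-6
            assert np.allclose(fe2.cse.rho, fe.cse.rho, atol=1e-6)

    def test_unobservable_model_is_infeasible(self):
        theta = stick_model(rho=0.0)
        sol = solve_nonobservation(theta)
        with pytest.raises(FEInfeasibleError):
            fe_map(theta, sol)


class TestFESimulation:
    def test_stick_conditional_and_unconditional_laws(self, rng):
        """Conditionally the output is always a stick; unconditionally it is
        a stick with probability rho and EMPTY otherwise."""
        theta = stick_model(rho=0.3, t_max=2.0)
        for _ in range(20):
            tree = simulate_reconstructed(theta, rng)
            assert not tree.is_empty and count_leaf_nodes(tree) == 1
            assert tree.total_branch_length() == pytest.approx(2.0)
        reps = 10_000
        empty = sum(simulate_reconstructed(theta, rng, conditional=False).is_empty
                    for _ in range(reps))
        se = math.sqrt(0.3 * 0.7 / reps)
        assert abs(empty / reps - 0.7) < 3 * se

    def test_outputs_satisfy_reconstructed_invariants(self, rng):
        """No deaths, no unsampled tips, every leaf a sampling event -- for
        random models including serial sampling and intermediate CSEs."""
        for _ in range(15):
            theta = random_model(rng)
            sol = solve_nonobservation(theta)
            if prob_nonempty(theta, sol) < 1e-3:
                continue
            tree = simulate_reconstructed(theta, rng)
            assert tree.is_reconstructed and tree.check() == []

    def test_matches_full_prune_with_serial_sampling_and_cse(self, rng):
        """Distributional equivalence where it is most delicate: serial
        sampling with survival (sampled ancestors) plus an intermediate CSE.
        This is the Monte-Carlo arbiter for the division form of the
        transformed psi and rho."""
        theta = BDMSParams(
            types=["A"], pi=[1.0], lam=[[0.8]], mu=[0.3], gamma=[[0.0]],
            psi=[0.4], r=[0.3],
            cse=CSESchedule(times=[0.0, 0.7], rho=[[0.4, 0.3]], q=[[0.0, 0.5]]),
            t_max=1.5)
        reps = 600
        full_leaves, full_events = [], []
        while len(full_leaves) < reps:
            rec = prune(simulate_full(theta, rng, validate=False)[0])
            if not rec.is_empty:
                full_leaves.append(count_leaf_nodes(rec))
                full_events.append(len(rec) - 1)
        fe_leaves, fe_events = [], []
        for _ in range(reps):
            tree = simulate_reconstructed(theta, rng)
            fe_leaves.append(count_leaf_nodes(tree))
            fe_events.append(len(tree) - 1)
        assert sps.ks_2samp(full_leaves, fe_leaves).pvalue > 0.001
        assert sps.ks_2samp(full_events, fe_events).pvalue > 0.001
        assert sps.mannwhitneyu(full_events, fe_events).pvalue > 0.001

    def test_finite_capacity_conditions_on_reconstructed_width(self, rng):
        """FE simulation with finite n_max draws from the full model
        conditioned on non-emptiness AND on maximal reconstructed width
        <= n_max (checked by rejection-sampling the full simulator)."""
        n_max = 3
        theta = single_type_model(1.5, 0.0, rho=0.6, t_max=1.0)
        capped = single_type_model(1.5, 0.0, rho=0.6, t_max=1.0, n_max=n_max)
        reps = 500
        full_leaves = []
        while len(full_leaves) < reps:
            rec = prune(simulate_full(theta, rng, validate=False)[0])
            if not rec.is_empty and max_width(rec) <= n_max:
                full_leaves.append(count_leaf_nodes(rec))
        fe_leaves = []
        for _ in range(reps):
            tree = simulate_reconstructed(capped, rng)
            assert max_width(tree) <= n_max
            fe_leaves.append(count_leaf_nodes(tree))
        assert sps.ks_2samp(full_leaves, fe_leaves).pvalue > 0.001

    def test_conditioning_on_impossible_observation_raises(self, rng):
        theta = stick_model(rho=0.0)
        with pytest.raises(FEInfeasibleError):
            simulate_reconstructed(theta, rng)
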