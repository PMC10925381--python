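"""Full-population simulator: waiting-time laws, event-category mix,
reference tree shapes, and structural invariants."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from phylofe import get_next_event, simulate_full
from phylofe.params import BDMSParams, CSESchedule
from phylofe.presets import single_type_model, stick_model
from phylofe.tree import (BIRTH, CSE_SAMPLE_DIE, CSE_SAMPLE_SURVIVE, DEATH,
                          MUTATION, PRESENT_UNSAMPLED_TIP, ROOT)

from conftest import random_model


class TestGetNextEvent:
    def test_homogeneous_waiting_time_is_exponential(self, rng):
        """Superposition of n independent constant-rate lineages waits
        Exp(n * total per-capita rate)."""
        theta = single_type_model(0.7, 0.2, psi=0.3, rho=1.0, t_max=1000.0)
        n, total = 5, 5 * (0.7 + 0.2 + 0.3)
        draws = 100_000
        waits = np.empty(draws)
        for i in range(draws):
            ev = get_next_event(theta, (n,), 1000.0, 0.0, rng)
            waits[i] = 1000.0 - ev.tau
        se = waits.std() / math.sqrt(draws)
        assert abs(waits.mean() - 1 / total) < 3 * se

    def test_category_probability_matches_intensity_share(self, rng,
                                                          validation_model):
        """From one Fit lineage, P(next event is a Fit->Unfit mutation)
        = 0.8 / (1 + 0.25 + 0.8)."""
        p_expected = 0.8 / (1 + 0.25 + 0.8)
        draws = 20_000
        hits = 0
        for _ in range(draws):
            ev = get_next_event(validation_model, (1, 0), 20.0, 0.0, rng)
            if not ev.none_before and ev.kind == "mutation" and ev.child_type == 1:
                hits += 1
        # events before tau=0 are near-certain here (rate 2.05 over 20 units)
        p_hat = hits / draws
        se = math.sqrt(p_expected * (1 - p_expected) / draws)
        assert abs(p_hat - p_expected) < 3 * se

    def test_piecewise_rate_event_times_follow_integrated_intensity(self, rng):
        """lam(tau)=2 on (0.5, 1], 0 on [0, 0.5]: all events land in
        (0.5, 1] and the law matches exact inversion of the integrated
        intensity (KS at alpha=0.001)."""
        theta = BDMSParams(
            types=["A"], pi=[1.0],
            lam=[[{"breakpoints": [0.5], "values": [0.0, 2.0]}]],
            mu=[0.0], gamma=[[0.0]], psi=[0.0], r=[0.0],
            cse=CSESchedule.present_only([1.0]), t_max=1.0)
        draws = 10_000
        times = []
        for _ in range(draws):
            ev = get_next_event(theta, (1,), 1.0, 0.0, rng)
            if not ev.none_before:
                times.append(ev.tau)
        times = np.array(times)
        assert times.min() > 0.5
        # waiting time w = 1 - tau is truncated Exp(2) on (0, 0.5]
        p = sps.kstest(1.0 - times, lambda w: (1 - np.exp(-2 * w)) / (1 - np.exp(-1))).pvalue
        assert p > 0.001
        # occurrence probability itself
        p_occ = len(times) / draws
        se = math.sqrt(p_occ * (1 - p_occ) / draws)
        assert abs(p_occ - (1 - math.exp(-1.0))) < 3 * se

    def test_grid_rate_uses_thinning_and_matches_inversion(self, rng):
        """A linearly increasing intensity lam(tau) = tau on [0, 1] sampled
        by thinning matches the closed-form inversion law."""
        from phylofe import GridRate
        theta = BDMSParams(
            types=["A"], pi=[1.0], lam=[[GridRate([0.0, 1.0], [0.0, 1.0])]],
            mu=[0.0], gamma=[[0.0]], psi=[0.0], r=[0.0],
            cse=CSESchedule.present_only([1.0]), t_max=1.0)
        draws = 10_000
        waits = []
        for _ in range(draws):
            ev = get_next_event(theta, (1,), 1.0, 0.0, rng)
            if not ev.none_before:
                waits.append(1.0 - ev.tau)
        # integrated intensity from tau=1 downward: Lambda(w) = w - w^2/2
        total = 0.5
        p = sps.kstest(np.array(waits),
                       lambda w: (1 - np.exp(-(w - w**2 / 2))) / (1 - np.exp(-total))).pvalue
        assert p > 0.001

    def test_zero_rate_returns_none_before(self, rng):
        theta = stick_model()
        ev = get_next_event(theta, (1,), 1.0, 0.0, rng)
        assert ev.none_before and ev.tau == 0.0

    def test_requires_ordered_window(self, rng, stick):
        with pytest.raises(ValueError, match="tau_floor < tau_now"):
            get_next_event(stick, (1,), 0.0, 1.0, rng)


class TestSimulateFull:
    def test_stick_process_yields_single_stick(self, rng):
        theta = stick_model(rho=1.0, t_max=3.0)
        tree, cap = simulate_full(theta, rng)
        assert not cap
        events = [n.event for n in tree.preorder()]
        assert events == [ROOT, CSE_SAMPLE_SURVIVE] or events == [ROOT, CSE_SAMPLE_DIE]
        assert tree.total_branch_length() == pytest.approx(3.0)

    def test_yule_mean_sampled_leaves_is_exponential_growth(self, rng, yule):
        """E[present-day lineages] = e^{lam * t} for a pure-birth process."""
        reps = 10_000
        leaves = np.empty(reps)
        for i in range(reps):
            tree, _ = simulate_full(yule, rng, validate=False)
            leaves[i] = sum(1 for n in tree.nodes.values() if not n.children)
        se = leaves.std() / math.sqrt(reps)
        assert abs(leaves.mean() - math.e) < 3 * se

    def test_critical_survival_probability(self, rng):
        """P(>= 1 lineage survives to the present) = 1/(1 + lam t) at
        criticality."""
        theta = single_type_model(1.0, 1.0, rho=1.0, t_max=10.0)
        reps = 10_000
        survived = 0
        for _ in range(reps):
            tree, _ = simulate_full(theta, rng, validate=False)
            survived += any(
                n.event in (CSE_SAMPLE_SURVIVE, CSE_SAMPLE_DIE, PRESENT_UNSAMPLED_TIP)
                for n in tree.nodes.values())
        p, p_hat = 1 / 11, survived / reps
        se = math.sqrt(p * (1 - p) / reps)
        assert abs(p_hat - p) < 3 * se

    def test_capacity_guard_returns_partial_tree_with_flag(self, rng):
        theta = single_type_model(5.0, 0.0, rho=1.0, t_max=10.0, n_max=16)
        tree, cap = simulate_full(theta, rng)
        assert cap and len(tree) > 16

    def test_structural_invariants_on_random_models(self, rng):
        """Every emitted tree satisfies the node/tree invariants; with no
        serial sampling and no intermediate CSE, internal nodes are births or
        mutations and every tip is a death, an unsampled survivor, or a
        present-day sample."""
        for _ in range(30):
            theta = random_model(rng, allow_psi=False, allow_cse=False)
            tree, cap = simulate_full(theta, rng)
            assert tree.check() == []
            if cap:
                continue
            for n in tree.nodes.values():
                if n.event == ROOT:
                    continue
                if n.children:
                    assert n.event in (BIRTH, MUTATION)
                else:
                    assert n.event in (DEATH, PRESENT_UNSAMPLED_TIP,
                                       CSE_SAMPLE_SURVIVE, CSE_SAMPLE_DIE)

    def test_invalid_parameters_rejected(self, validation_model):
        validation_model.pi = np.array([0.6, 0.6])
        with pytest.raises(ValueError, match="invalid BDMS parameters"):
            simulate_full(validation_model, np.random.default_rng(0))
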