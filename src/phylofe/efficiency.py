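"""Speedup accounting for the forward-equivalent simulation.

The cost of either pipeline is proportional to the expected number of
simulated events per non-empty reconstructed tree: R for the full pipeline
(which pays for unobserved lineages and for empty-tree retries), R_FE for the
forward-equivalent one.  The ratio satisfies

    R / R_FE = E[#nodes(T)] / E[#nodes(R(T))]

where T is the full tree, R(T) its (possibly empty) reconstructed tree, and
node counts include birth, death, mutation and sampling events plus one
event per present-day survivor (each is advanced and Bernoulli-sampled);
only the stem-origin marker is excluded.
For a single-type birth-death process run for one unit of time with extant
sampling probability rho the ratio has a closed form (see
:func:`speedup_single_type`); in general both expectations follow from the
linear mean-field ODE for expected per-type extant counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fe import fe_map
from .fullsim import simulate_full
from .nonobs import NonObsSolution, prob_nonempty, solve_nonobservation
from .params import BDMSParams
from .pruning import prune
from .tree import ROOT, Tree

__all__ = [
    "SpeedupReport",
    "speedup_single_type",
    "expected_node_counts",
    "empirical_node_ratio",
    "count_event_nodes",
]

#: |lam - mu| below which the critical branch of the closed form applies
_CRITICAL_SWITCH = 1e-8


def count_event_nodes(tree: Tree) -> int:
    """Number of simulated events in a tree: every node except the stem
    origin.  Present-day tip markers count whether or not they were sampled
    -- the simulator spends one event's worth of work advancing and
    Bernoulli-sampling each survivor, which is what makes the trivial
    stick process cost Theta(1) per attempt and hence speed up by 1/rho."""
    if tree.is_empty:
        return 0
    return sum(1 for n in tree.nodes.values() if n.event != ROOT)


def count_leaf_nodes(tree: Tree) -> int:
    """Number of leaves (terminal lineages) of a tree; 0 for EMPTY.  The
    closed form of :func:`speedup_single_type` is exactly the ratio of
    expected full to expected reconstructed leaf counts."""
    if tree.is_empty:
        return 0
    return sum(1 for n in tree.nodes.values() if not n.children)


def speedup_single_type(lam: float, mu: float, rho: float) -> float:
    """Closed-form R/R_FE for a single-type birth-death process run for one
    unit of time with extant sampling probability ``rho``:

    ``(1/rho)(1 + mu)`` at criticality ``lam = mu``, and otherwise
    ``(1/rho) [1 + mu (e^{lam-mu} - 1) / ((lam-mu) e^{lam-mu})]``; the two
    branches agree in the ``lam -> mu`` limit.
    """
    if lam < 0 or mu < 0:
        raise ValueError("rates must be nonnegative")
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    delta = lam - mu
    if abs(delta) < _CRITICAL_SWITCH:
        return (1.0 + mu) / rho
    return (1.0 + mu * (math.exp(delta) - 1.0) / (delta * math.exp(delta))) / rho


# ---------------------------------------------------------------------------
# mean-field expected node counts
# ---------------------------------------------------------------------------

def _mean_counts_and_nodes(theta: BDMSParams, steps_per_unit: int) -> float:
    """Expected number of event nodes of one full-simulation replicate,
    from the linear mean-field ODE for expected per-type extant counts.

    Going forward in biological time (decreasing tau), the expected counts
    ``m_a`` satisfy

        -dm_a/dtau = sum_b m_b lam_ba - m_a mu_a - m_a psi_a r_a
                     + sum_b m_b gamma_ba - m_a sum_b gamma_ab,

    and the expected node count is the integral of the total event intensity
    ``sum_a m_a (sum_b lam_ab + mu_a + psi_a + sum_b gamma_ab)`` plus, at each
    CSE, the expected number of sampled lineages ``sum_a m_a rho_al`` (after
    which ``m_a`` is thinned by ``1 - rho_al q_al``).
    """
    d = theta.d
    times = theta.cse.times
    m = theta.pi.astype(float).copy()
    nodes = 0.0

    def apply_cse(l: int):
        nonlocal m, nodes
        if theta.cse.times[l] == 0.0:
            # every present-day survivor becomes a tip node, sampled or not
            nodes += float(m.sum())
        else:
            nodes += float(m @ theta.cse.rho[:, l])
        m = m * (1.0 - theta.cse.rho[:, l] * theta.cse.q[:, l])

    # CSE exactly at the origin applies to the root immediately
    for l in range(times.size - 1, -1, -1):
        if times[l] == theta.t_max:
            apply_cse(l)

    # inter-CSE intervals, descending tau
    edges = [(times[l], l) for l in range(times.size - 1, -1, -1)
             if times[l] < theta.t_max]
    hi = theta.t_max
    for lo, l in edges:
        if hi > lo:
            n = max(int(math.ceil((hi - lo) * steps_per_unit)), 10)
            grid = np.linspace(hi, lo, n + 1)  # descending tau
            h = (hi - lo) / n
            tall = np.empty(2 * n + 1)
            tall[0::2] = grid
            tall[1::2] = grid[:-1] - 0.5 * h
            L = np.empty((tall.size, d, d))
            G = np.empty((tall.size, d, d))
            mu = np.empty((tall.size, d))
            psi = np.empty((tall.size, d))
            rr = np.empty((tall.size, d))
            for a in range(d):
                mu[:, a] = theta.mu[a].value_at(tall)
                psi[:, a] = theta.psi[a].value_at(tall)
                rr[:, a] = theta.r[a].value_at(tall)
                for b in range(d):
                    L[:, a, b] = theta.lam[a][b].value_at(tall)
                    G[:, a, b] = theta.gamma[a][b].value_at(tall)
            Lrow = L.sum(axis=2)
            Grow = G.sum(axis=2)
            h_tot = Lrow + mu + psi + Grow  # per-capita event intensity

            def rhs(mvec, i):
                born = mvec @ L[i]           # sum_b m_b lam_{b,a}
                mut_in = mvec @ G[i]
                return (born - mvec * (mu[i] + psi[i] * rr[i])
                        + mut_in - mvec * Grow[i])

            intensity = np.empty(n + 1)
            intensity[0] = float(m @ h_tot[0])
            for k in range(n):
                i0, i1, i2 = 2 * k, 2 * k + 1, 2 * k + 2
                k1 = rhs(m, i0)
                k2 = rhs(m + 0.5 * h * k1, i1)
                k3 = rhs(m + 0.5 * h * k2, i1)
                k4 = rhs(m + h * k3, i2)
                m = m + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                intensity[k + 1] = float(m @ h_tot[i2])
            nodes += float(np.trapezoid(intensity[::-1], grid[::-1]))
        apply_cse(l)
        hi = lo
    return nodes


def expected_node_counts(theta: BDMSParams, sol: NonObsSolution | None = None,
                         steps_per_unit: int = 256) -> tuple[float, float]:
    """(E[#nodes(T)], E[#nodes(R(T))]) by time discretization of the
    mean-field ODE; the reconstructed expectation runs the same computation
    under F(theta) and rescales by the non-emptiness probability (the
    forward-equivalent simulator conditions on non-emptiness)."""
    if sol is None:
        sol = solve_nonobservation(theta)
    full_nodes = _mean_counts_and_nodes(theta, steps_per_unit)
    fe = fe_map(theta, sol)
    rec_nodes = _mean_counts_and_nodes(fe, steps_per_unit) * prob_nonempty(theta, sol)
    return full_nodes, rec_nodes


# ---------------------------------------------------------------------------
# Monte-Carlo estimate
# ---------------------------------------------------------------------------

@dataclass
class SpeedupReport:
    """R, R_FE and their ratio, with standard errors when stochastic."""

    ratio: float
    R: float | None = None
    R_FE: float | None = None
    method: str = "closed_form"
    se_ratio: float | None = None
    reps: int | None = None
    p_nonempty: float | None = None
    capacity_exceedances: int = 0
    #: ratio of mean full-tree to mean reconstructed-tree leaf counts
    leaf_ratio: float | None = None
    se_leaf_ratio: float | None = None


def _ratio_of_means(x: np.ndarray, y: np.ndarray) -> tuple[float, float | None]:
    """mean(x)/mean(y) with its delta-method standard error (None at n=1)."""
    n = x.size
    mx, my = x.mean(), y.mean()
    if my <= 0:
        return math.inf, None
    ratio = mx / my
    if n < 2:
        return ratio, None
    cov = np.cov(x, y)
    var = (cov[0, 0] - 2 * ratio * cov[0, 1] + ratio**2 * cov[1, 1]) / (n * my**2)
    return ratio, math.sqrt(max(var, 0.0))


def empirical_node_ratio(theta: BDMSParams, reps: int,
                         rng: np.random.Generator) -> SpeedupReport:
    """Monte-Carlo estimate of R/R_FE from ``reps`` full simulations.

    Empty reconstructed trees contribute zero nodes to the reconstructed
    mean.  The standard error of the ratio of means uses the delta method
    with the empirical covariance of the paired per-replicate counts.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    x = np.empty(reps)
    y = np.empty(reps)
    xl = np.empty(reps)
    yl = np.empty(reps)
    nonempty = 0
    exceeded = 0
    for i in range(reps):
        tree, cap = simulate_full(theta, rng, validate=i == 0)
        exceeded += cap
        x[i] = count_event_nodes(tree)
        xl[i] = count_leaf_nodes(tree)
        rec = prune(tree)
        y[i] = count_event_nodes(rec)
        yl[i] = count_leaf_nodes(rec)
        nonempty += not rec.is_empty
    ratio, se = _ratio_of_means(x, y)
    leaf_ratio, se_leaf = _ratio_of_means(xl, yl)
    p_ne = nonempty / reps
    return SpeedupReport(
        ratio=ratio,
        R=x.mean() / p_ne if p_ne > 0 else math.inf,
        R_FE=y.mean() / p_ne if p_ne > 0 else math.inf,
        method="monte_carlo", se_ratio=se, reps=reps, p_nonempty=p_ne,
        capacity_exceedances=exceeded,
        leaf_ratio=leaf_ratio, se_leaf_ratio=se_leaf,
    )
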