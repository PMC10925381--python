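"""The forward-equivalent transformation and simulator.

For any BDMS model Theta with positive non-emptiness probability there is a
model Theta_FE with *no death* and *complete sampling at the present* whose
(full = reconstructed) tree has the law of Theta's reconstructed tree
conditioned on being non-empty.  Writing ``E_a`` for the non-observation
probability and ``p_a = 1 - E_a`` for the observation probability, the map is

    pi_FE_a       = pi_a p_a(t_max) / sum_b pi_b p_b(t_max)
    lam_FE_ab     = p_b lam_ab                      (births with both
                                                     daughters observed)
    mu_FE_a       = 0
    psi_FE_a      = psi_a / p_a                     (a serial sample is always
                                                     observed)
    r_FE_a        = r_a + (1 - r_a) E_a             (unobserved continuations
                                                     are truncated)
    gamma_FE_ab   = (p_b / p_a) (gamma_ab + E_a lam_ab)   for b != a
                                                    (includes births whose
                                                     same-type daughter went
                                                     unobserved)
    rho_FE_al     = rho_al / p_a(t_l+),   q_FE_al = q_al + (1 - q_al) E_a(t_l-)

so in particular ``rho_FE_{a,0} = rho_{a,0} / (1 - (1 - rho_{a,0})) = 1``.
The psi and rho entries divide by the observation probability: conditioning a
lineage on being observed *raises* the apparent sampling rates.  (The
multiplicative reading of these two entries is inconsistent with complete
present-day sampling and is rejected by the Monte-Carlo equivalence tests.)

Transformed rates are realized as exact closures over the PCHIP interpolant
of E, with thinning upper bounds obtained from the interpolation-grid extrema.
"""

from __future__ import annotations

import numpy as np

from .fullsim import simulate_full
from .nonobs import NonObsSolution, prob_nonempty, solve_nonobservation
from .params import BDMSParams, CSESchedule, validate_params
from .rates import ConstantRate, RateFunction
from .tree import Tree

__all__ = ["FEParams", "FEInfeasibleError", "fe_map", "simulate_reconstructed",
           "clear_fe_cache"]

DEFAULT_OBS_FLOOR = 1e-12


class FEInfeasibleError(ValueError):
    """A needed division by an observation probability fell below the floor
    (the lineage type is essentially never observed)."""


class _FERate(RateFunction):
    """Base for transformed rates: continuous within inter-CSE intervals,
    with possible jumps at interior CSE times and at base-rate breakpoints."""

    is_piecewise_constant = False

    def __init__(self, sol: NonObsSolution, bases: tuple[RateFunction, ...]):
        self.sol = sol
        self.bases = bases

    def jump_points(self, lo, hi):
        pts = set()
        for f in self.bases:
            pts.update(f.jump_points(lo, hi))
        pts.update(t for t in self.sol.cse_times if lo < t < hi)
        return sorted(pts)

    def fingerprint(self):
        return (type(self).__name__, id(self.sol),
                tuple(f.fingerprint() for f in self.bases))


class FEBirthRate(_FERate):
    """lam_FE_ab = (1 - E_b) lam_ab."""

    def __init__(self, sol, lam_ab: RateFunction, b: int):
        super().__init__(sol, (lam_ab,))
        self.b = b

    def value_at(self, tau):
        return self.bases[0].value_at(tau) * (1.0 - self.sol.E_at(self.b, tau, side="plus"))

    def upper_bound_on(self, lo, hi):
        emin, _ = self.sol.E_extrema(self.b, lo, hi)
        return self.bases[0].upper_bound_on(lo, hi) * (1.0 - emin)

    def is_zero(self):
        return self.bases[0].is_zero()


class FEPsiRate(_FERate):
    """psi_FE_a = psi_a / (1 - E_a)."""

    def __init__(self, sol, psi_a: RateFunction, a: int, floor: float):
        super().__init__(sol, (psi_a,))
        self.a = a
        self.floor = floor

    def value_at(self, tau):
        p = np.maximum(1.0 - self.sol.E_at(self.a, tau, side="plus"), self.floor)
        return self.bases[0].value_at(tau) / p

    def upper_bound_on(self, lo, hi):
        _, emax = self.sol.E_extrema(self.a, lo, hi)
        return self.bases[0].upper_bound_on(lo, hi) / max(1.0 - emax, self.floor)

    def is_zero(self):
        return self.bases[0].is_zero()


class FEGammaRate(_FERate):
    """gamma_FE_ab = ((1 - E_b) / (1 - E_a)) (gamma_ab + E_a lam_ab), b != a."""

    def __init__(self, sol, gamma_ab: RateFunction, lam_ab: RateFunction,
                 a: int, b: int, floor: float):
        super().__init__(sol, (gamma_ab, lam_ab))
        self.a = a
        self.b = b
        self.floor = floor

    def value_at(self, tau):
        Ea = self.sol.E_at(self.a, tau, side="plus")
        Eb = self.sol.E_at(self.b, tau, side="plus")
        pa = np.maximum(1.0 - Ea, self.floor)
        return (1.0 - Eb) / pa * (
            self.bases[0].value_at(tau) + Ea * self.bases[1].value_at(tau)
        )

    def upper_bound_on(self, lo, hi):
        ea_min, ea_max = self.sol.E_extrema(self.a, lo, hi)
        eb_min, _ = self.sol.E_extrema(self.b, lo, hi)
        num = self.bases[0].upper_bound_on(lo, hi) + ea_max * self.bases[1].upper_bound_on(lo, hi)
        return (1.0 - eb_min) / max(1.0 - ea_max, self.floor) * num

    def is_zero(self):
        return self.bases[0].is_zero() and self.bases[1].is_zero()


class FERFunction(_FERate):
    """r_FE_a = r_a + (1 - r_a) E_a, a [0, 1]-valued death-given-sampled
    probability: unobserved continuations after a serial sample are cut."""

    def __init__(self, sol, r_a: RateFunction, a: int):
        super().__init__(sol, (r_a,))
        self.a = a

    def value_at(self, tau):
        r = self.bases[0].value_at(tau)
        Ea = self.sol.E_at(self.a, tau, side="plus")
        return np.clip(r + (1.0 - r) * Ea, 0.0, 1.0)

    def upper_bound_on(self, lo, hi):
        return 1.0


class FEParams(BDMSParams):
    """A BDMS parameter bundle produced by the forward-equivalent map, with
    provenance links to the source model and its ODE solution."""

    def __init__(self, *args, source: BDMSParams, solution: NonObsSolution,
                 p_nonempty: float, **kwargs):
        super().__init__(*args, **kwargs)
        self.source = source
        self.solution = solution
        self.p_nonempty = p_nonempty


def fe_map(theta: BDMSParams, sol: NonObsSolution | None = None, *,
           obs_floor: float = DEFAULT_OBS_FLOOR,
           steps_per_unit: int | None = None) -> FEParams:
    """Apply the forward-equivalent map F to ``theta``.

    ``sol`` may be passed to reuse a solved non-observation ODE; otherwise it
    is solved here.  Raises :class:`FEInfeasibleError` when the non-emptiness
    probability is zero, or when a transformed rate would divide by an
    observation probability below ``obs_floor`` at a time where its numerator
    is not identically zero.
    """
    if sol is None:
        kw = {} if steps_per_unit is None else {"steps_per_unit": steps_per_unit}
        sol = solve_nonobservation(theta, **kw)
    d = theta.d

    w = theta.pi * (1.0 - sol.E_final)
    p_ne = prob_nonempty(theta, sol)
    if w.sum() <= 0.0:
        raise FEInfeasibleError("prob_nonempty(theta) = 0: no observable tree exists")
    pi_fe = w / w.sum()

    # division guards: observation probability minima per type over [0, t_max]
    p_min = np.array([1.0 - sol.E_extrema(a, 0.0, theta.t_max)[1] for a in range(d)])

    def _guard(a: int, numerator_zero: bool, what: str):
        if not numerator_zero and p_min[a] < obs_floor:
            raise FEInfeasibleError(
                f"type {theta.types.labels[a]} has observation probability below "
                f"{obs_floor:g} somewhere on [0, t_max] but a nonzero {what}; "
                "the transformed rate would be unbounded"
            )

    lam_fe: list[list[RateFunction]] = [[None] * d for _ in range(d)]
    gamma_fe: list[list[RateFunction]] = [[None] * d for _ in range(d)]
    psi_fe: list[RateFunction] = [None] * d
    r_fe: list[RateFunction] = [None] * d
    for a in range(d):
        _guard(a, theta.psi[a].is_zero(), "serial sampling rate psi")
        psi_fe[a] = (ConstantRate(0.0) if theta.psi[a].is_zero()
                     else FEPsiRate(sol, theta.psi[a], a, obs_floor))
        r_fe[a] = FERFunction(sol, theta.r[a], a)
        for b in range(d):
            lam_fe[a][b] = (ConstantRate(0.0) if theta.lam[a][b].is_zero()
                            else FEBirthRate(sol, theta.lam[a][b], b))
            if a == b:
                gamma_fe[a][b] = ConstantRate(0.0)
            else:
                numer_zero = theta.gamma[a][b].is_zero() and theta.lam[a][b].is_zero()
                _guard(a, numer_zero, f"mutation/cladogenesis rate toward "
                                      f"{theta.types.labels[b]}")
                gamma_fe[a][b] = (ConstantRate(0.0) if numer_zero
                                  else FEGammaRate(sol, theta.gamma[a][b],
                                                   theta.lam[a][b], a, b, obs_floor))

    L1 = theta.cse.times.size
    rho_fe = np.zeros((d, L1))
    q_fe = np.zeros((d, L1))
    for l in range(L1):
        E_minus, E_plus = sol.cse_limits[l]
        for a in range(d):
            rho = theta.cse.rho[a, l]
            denom = 1.0 - E_plus[a]
            rho_fe[a, l] = 0.0 if rho == 0.0 else min(rho / max(denom, obs_floor), 1.0)
            q = theta.cse.q[a, l]
            q_fe[a, l] = min(q + (1.0 - q) * E_minus[a], 1.0)

    cse_fe = CSESchedule(times=theta.cse.times.copy(), rho=rho_fe, q=q_fe)
    mu_fe = [ConstantRate(0.0) for _ in range(d)]
    return FEParams(
        theta.types, pi_fe, lam_fe, mu_fe, gamma_fe, psi_fe, r_fe, cse_fe,
        theta.t_max, n_max=theta.n_max,
        name=(theta.name + "-FE") if theta.name else "FE",
        source=theta, solution=sol, p_nonempty=p_ne,
    )


# ---------------------------------------------------------------------------
# forward-equivalent simulation
# ---------------------------------------------------------------------------

_FE_CACHE: dict = {}


def clear_fe_cache() -> None:
    _FE_CACHE.clear()


def _cached_fe(theta: BDMSParams) -> tuple[NonObsSolution, FEParams]:
    """The ODE solve and map F are computed once per parameter bundle and
    reused across replicates."""
    key = theta.fingerprint()
    if key not in _FE_CACHE:
        sol = solve_nonobservation(theta)
        _FE_CACHE[key] = (sol, fe_map(theta, sol))
    return _FE_CACHE[key]


def simulate_reconstructed(theta: BDMSParams, rng: np.random.Generator, *,
                           conditional: bool = True,
                           validate: bool = True,
                           max_capacity_retries: int = 1000) -> Tree:
    """Simulate a reconstructed phylogeny of ``theta`` directly.

    With ``conditional=True`` the result is distributed as the reconstructed
    tree conditioned on non-emptiness (never EMPTY); otherwise a Bernoulli
    draw with the non-emptiness probability first decides whether to return
    the EMPTY sentinel.  A finite ``theta.n_max`` additionally conditions on
    the reconstructed tree's maximal width not exceeding ``n_max``
    (capacity-exceeded replicates are rejected and redrawn).
    """
    if validate:
        problems = validate_params(theta)
        if problems:
            raise ValueError("invalid BDMS parameters: " + "; ".join(problems))
    sol, fe = _cached_fe(theta)
    if fe.p_nonempty <= 0.0 and conditional:
        raise FEInfeasibleError("cannot condition on non-emptiness: P(nonempty) = 0")
    if not conditional and rng.random() >= fe.p_nonempty:
        return Tree.empty(theta.types.labels)
    for _ in range(max_capacity_retries):
        tree, exceeded = simulate_full(fe, rng, validate=False)
        if not exceeded:
            tree.is_reconstructed = True
            return tree
    raise RuntimeError(
        f"capacity n_max={theta.n_max} exceeded {max_capacity_retries} times in a row"
    )
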