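"""Non-observation probabilities E_a(tau) and the non-emptiness probability.

``E_a(tau)`` is the probability that a type-``a`` lineage alive at
time-before-present ``tau`` leaves no sampled descendant.  Between CSEs it
solves, in increasing ``tau``,

    dE_a/dtau = sum_b lam_ab(tau) (E_a E_b - E_a)
              + mu_a(tau) (1 - E_a)
              - psi_a(tau) E_a
              + sum_b gamma_ab(tau) (E_b - E_a),

with initialization E_a(0-) = 1 and, at each CSE time t_l (including the
present-day CSE at t_0 = 0), the jump E_a(t_l+) = (1 - rho_al) E_a(t_l-),
where the minus side is the post-CSE (smaller-``tau``) limit and the plus
side the pre-CSE one.  The probability that the reconstructed tree is
non-empty is ``1 - sum_a pi_a E_a(t_max)``.

The integrator is classical fixed-step RK4 on a uniform grid within each
inter-CSE interval; the grid doubles as the interpolation grid for the
forward-equivalent rates.  Interpolation between grid points is monotone
piecewise cubic (PCHIP), whose values never leave the range of the local
grid values -- which is what makes cheap, safe upper bounds for Poisson
thinning possible downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .params import BDMSParams, validate_params

__all__ = ["NonObsSolution", "NumericalError", "solve_nonobservation", "prob_nonempty"]

DEFAULT_STEPS_PER_UNIT = 512
MIN_STEPS_PER_INTERVAL = 10


class NumericalError(RuntimeError):
    """Raised when grid refinement does not meet the requested tolerance."""

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


@dataclass
class _Interval:
    lo: float
    hi: float
    grid: np.ndarray          # ascending taus, grid[0] = lo, grid[-1] = hi
    E: np.ndarray             # shape (d, len(grid)); one-sided at the edges
    _pchip: dict = field(default_factory=dict, repr=False)

    def interp(self, a: int):
        if a not in self._pchip:
            self._pchip[a] = PchipInterpolator(self.grid, self.E[a], extrapolate=False)
        return self._pchip[a]

    def eval_scalar(self, a: int, tau: float) -> float:
        """Cubic evaluation from the PCHIP coefficients, avoiding the
        array-call overhead of the interpolator (hot path of thinning)."""
        pp = self.interp(a)
        i = int(np.searchsorted(self.grid, tau, side="right")) - 1
        i = min(max(i, 0), self.grid.size - 2)
        dt = tau - self.grid[i]
        c = pp.c
        return float(((c[0, i] * dt + c[1, i]) * dt + c[2, i]) * dt + c[3, i])


@dataclass
class NonObsSolution:
    """Per-type non-observation probabilities on a grid, with one-sided
    limits at CSE times."""

    d: int
    t_max: float
    cse_times: np.ndarray
    intervals: list[_Interval]
    #: per CSE l: (E(t_l-), E(t_l+)) as length-d arrays (post- and pre-CSE)
    cse_limits: list[tuple[np.ndarray, np.ndarray]]
    #: E at t_max, after the jump of a CSE at exactly t_max if one exists
    E_final: np.ndarray
    steps_per_unit: int
    _interval_los: np.ndarray = field(default=None, repr=False)
    _scalar_cache_key: tuple | None = field(default=None, repr=False)
    _scalar_cache_val: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._interval_los = np.array([iv.lo for iv in self.intervals])

    def _interval_index(self, tau: np.ndarray, side: str) -> np.ndarray:
        los = self._interval_los
        s = "right" if side == "plus" else "left"
        idx = np.searchsorted(los, tau, side=s) - 1
        return np.clip(idx, 0, len(self.intervals) - 1)

    def _E_scalar(self, a: int, tau: float, side: str) -> float:
        key = (tau, side)
        if self._scalar_cache_key != key:
            self._scalar_cache_key = key
            self._scalar_cache_val = {}
        cached = self._scalar_cache_val.get(a)
        if cached is not None:
            return cached
        if tau <= 0.0:
            val = 1.0 if side == "minus" else float(self.cse_limits[0][1][a])
        elif side == "plus" and tau >= self.t_max:
            val = float(self.E_final[a])
        else:
            tau = min(tau, self.t_max)
            los = self._interval_los
            s = "right" if side == "plus" else "left"
            i = min(max(int(np.searchsorted(los, tau, side=s)) - 1, 0),
                    len(self.intervals) - 1)
            val = min(max(self.intervals[i].eval_scalar(a, tau), 0.0), 1.0)
        self._scalar_cache_val[a] = val
        return val

    def E_at(self, a: int, tau, side: str = "minus"):
        """E_a at ``tau``.  At a CSE time the ``side`` picks the limit:
        ``"minus"`` (default) the post-CSE value approached from below,
        ``"plus"`` the pre-CSE value (used by the forward-equivalent map).
        """
        if side not in ("minus", "plus"):
            raise ValueError("side must be 'minus' or 'plus'")
        if np.ndim(tau) == 0:
            return self._E_scalar(a, float(tau), side)
        scalar = False
        tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
        tau_arr = np.clip(tau_arr, 0.0, self.t_max)
        out = np.empty_like(tau_arr)
        idx = self._interval_index(tau_arr, side)
        for i in np.unique(idx):
            mask = idx == i
            out[mask] = self.intervals[i].interp(a)(tau_arr[mask])
        # outside any interval / one-sided specials
        out[tau_arr <= 0] = 1.0 if side == "minus" else self.cse_limits[0][1][a]
        if side == "plus":
            out[tau_arr >= self.t_max] = self.E_final[a]
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def E_extrema(self, a: int, lo: float, hi: float) -> tuple[float, float]:
        """(min, max) of E_a over [lo, hi]; exact for the PCHIP interpolant,
        whose values never leave the range of the covered grid values."""
        cands = [self.E_at(a, lo, side="plus"), self.E_at(a, hi, side="minus")]
        for iv in self.intervals:
            if iv.hi <= lo or iv.lo >= hi:
                continue
            i0 = int(np.searchsorted(iv.grid, lo, side="left"))
            i1 = int(np.searchsorted(iv.grid, hi, side="right"))
            if i1 > i0:
                vals = iv.E[a][i0:i1]
                cands.extend((float(vals.min()), float(vals.max())))
        return min(cands), max(cands)

    def grid_all(self) -> np.ndarray:
        return np.concatenate([iv.grid for iv in self.intervals])


def _rhs(E, L, Lrow, mu, psi, G, Grow):
    return E * (L @ E) - E * Lrow + mu * (1.0 - E) - psi * E + G @ E - E * Grow


def _integrate_interval(theta: BDMSParams, E0: np.ndarray, lo: float, hi: float,
                        steps_per_unit: int) -> _Interval:
    d = theta.d
    n = max(int(math.ceil((hi - lo) * steps_per_unit)), MIN_STEPS_PER_INTERVAL)
    grid = np.linspace(lo, hi, n + 1)
    h = (hi - lo) / n
    # rates evaluated once, vectorized, at grid and half-grid points
    tall = np.empty(2 * n + 1)
    tall[0::2] = grid
    tall[1::2] = grid[:-1] + 0.5 * h
    L = np.empty((tall.size, d, d))
    G = np.empty((tall.size, d, d))
    mu = np.empty((tall.size, d))
    psi = np.empty((tall.size, d))
    for a in range(d):
        mu[:, a] = theta.mu[a].value_at(tall)
        psi[:, a] = theta.psi[a].value_at(tall)
        for b in range(d):
            L[:, a, b] = theta.lam[a][b].value_at(tall)
            G[:, a, b] = theta.gamma[a][b].value_at(tall)
    Lrow = L.sum(axis=2)
    Grow = G.sum(axis=2)

    E = np.empty((d, n + 1))
    E[:, 0] = E0
    y = E0.copy()
    for k in range(n):
        i0, i1, i2 = 2 * k, 2 * k + 1, 2 * k + 2
        k1 = _rhs(y, L[i0], Lrow[i0], mu[i0], psi[i0], G[i0], Grow[i0])
        k2 = _rhs(y + 0.5 * h * k1, L[i1], Lrow[i1], mu[i1], psi[i1], G[i1], Grow[i1])
        k3 = _rhs(y + 0.5 * h * k2, L[i1], Lrow[i1], mu[i1], psi[i1], G[i1], Grow[i1])
        k4 = _rhs(y + h * k3, L[i2], Lrow[i2], mu[i2], psi[i2], G[i2], Grow[i2])
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        E[:, k + 1] = y
    np.clip(E, 0.0, 1.0, out=E)
    return _Interval(lo=lo, hi=hi, grid=grid, E=E)


def _solve_once(theta: BDMSParams, steps_per_unit: int) -> NonObsSolution:
    d = theta.d
    times = theta.cse.times
    E_cur = np.ones(d)
    cse_limits: list[tuple[np.ndarray, np.ndarray]] = []
    intervals: list[_Interval] = []
    for l in range(times.size):
        E_minus = E_cur.copy()
        E_plus = (1.0 - theta.cse.rho[:, l]) * E_minus
        cse_limits.append((E_minus, E_plus))
        E_cur = E_plus.copy()
        lo = times[l]
        hi = times[l + 1] if l + 1 < times.size else theta.t_max
        if hi > lo:
            iv = _integrate_interval(theta, E_cur, lo, hi, steps_per_unit)
            intervals.append(iv)
            E_cur = iv.E[:, -1].copy()
    return NonObsSolution(
        d=d, t_max=theta.t_max, cse_times=times.copy(), intervals=intervals,
        cse_limits=cse_limits, E_final=E_cur, steps_per_unit=steps_per_unit,
    )


def solve_nonobservation(theta: BDMSParams,
                         steps_per_unit: int = DEFAULT_STEPS_PER_UNIT,
                         tolerance: float | None = None,
                         validate: bool = True) -> NonObsSolution:
    """Solve the non-observation ODE system on a fixed grid.

    When ``tolerance`` is given, the solve is repeated at twice the
    resolution and the coarse/fine sup-discrepancy is required to be below
    it (otherwise :class:`NumericalError` reports the achieved error); the
    refined solution is returned.
    """
    if validate:
        problems = validate_params(theta)
        if problems:
            raise ValueError("invalid BDMS parameters: " + "; ".join(problems))
    sol = _solve_once(theta, steps_per_unit)
    if tolerance is None:
        return sol
    fine = _solve_once(theta, 2 * steps_per_unit)
    err = 0.0
    for ivc, ivf in zip(sol.intervals, fine.intervals):
        err = max(err, float(np.max(np.abs(ivc.E - ivf.E[:, ::2]))))
    if err > tolerance:
        raise NumericalError(
            f"grid refinement discrepancy {err:.3e} exceeds tolerance {tolerance:.3e}",
            achieved=err,
        )
    return fine


def prob_nonempty(theta: BDMSParams, sol: NonObsSolution) -> float:
    """P(reconstructed tree is non-empty) = 1 - sum_a pi_a E_a(t_max)."""
    return float(np.clip(1.0 - theta.pi @ sol.E_final, 0.0, 1.0))
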