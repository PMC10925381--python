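"""The BDMS parameter space.

A multi-type birth-death-mutation-sampling (BDMS) process over ``d`` types:
one lineage starts at time-before-present ``t_max`` with type drawn from
``pi``; a type-``a`` lineage splits into an ``a`` and a ``b`` daughter at rate
``lam[a][b](tau)``, dies at rate ``mu[a](tau)``, mutates anagenetically to
``b != a`` at rate ``gamma[a][b](tau)``, and is sampled serially at rate
``psi[a](tau)`` (dying on sampling with probability ``r[a](tau)``).
Concerted sampling events (CSEs) at fixed times ``t_0 = 0 < t_1 < ... <= t_max``
sample each extant type-``a`` lineage independently with probability
``rho[a][l]``, killing it with probability ``q[a][l]`` given sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rates import ConstantRate, RateFunction, as_rate

__all__ = [
    "TypeSpace",
    "CSESchedule",
    "BDMSParams",
    "validate_params",
    "total_event_rate",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class TypeSpace:
    """Ordered collection of distinct type labels."""

    labels: tuple[str, ...]

    def __init__(self, labels: Sequence[str]):
        object.__setattr__(self, "labels", tuple(str(x) for x in labels))

    @property
    def d(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def violations(self) -> list[str]:
        out = []
        if self.d < 1:
            out.append("type space must contain at least one type")
        if len(set(self.labels)) != self.d:
            out.append("type labels must be unique")
        bad = set("();,:[]=|'\"\t\n ")
        for lb in self.labels:
            if not lb or set(lb) & bad:
                out.append(
                    f"type label {lb!r} is empty or contains characters reserved "
                    "by the Newick/annotation serialization"
                )
        return out


@dataclass
class CSESchedule:
    """Concerted sampling events: times and per-type (rho, q) probabilities.

    ``times[0]`` must be exactly 0 (the present-day CSE always exists; use
    ``rho = 0`` for no present-day sampling).  ``rho`` and ``q`` are arrays of
    shape (d, L+1): ``rho[a, l]`` applies to type ``a`` at ``times[l]``.
    """

    times: np.ndarray
    rho: np.ndarray
    q: np.ndarray

    def __init__(self, times, rho, q):
        self.times = np.asarray(times, dtype=float)
        self.rho = np.atleast_2d(np.asarray(rho, dtype=float))
        self.q = np.atleast_2d(np.asarray(q, dtype=float))

    @property
    def n_events(self) -> int:
        return self.times.size

    @classmethod
    def present_only(cls, rho: Sequence[float], q: Sequence[float] | None = None):
        rho = np.asarray(rho, dtype=float).reshape(-1, 1)
        if q is None:
            q = np.zeros_like(rho)
        else:
            q = np.asarray(q, dtype=float).reshape(-1, 1)
        return cls(times=[0.0], rho=rho, q=q)

    def violations(self, d: int, t_max: float) -> list[str]:
        out = []
        t = self.times
        if t.size == 0 or t[0] != 0.0:
            out.append("CSE times must start with the present-day event at exactly 0")
        if np.any(np.diff(t) <= 0):
            out.append("CSE times must be strictly increasing")
        if t.size and t[-1] > t_max:
            out.append(f"CSE time {t[-1]} exceeds t_max={t_max}")
        for name, arr in (("rho", self.rho), ("q", self.q)):
            if arr.shape != (d, t.size):
                out.append(
                    f"CSE {name} must have shape (d={d}, L+1={t.size}), got {arr.shape}"
                )
            elif np.any((arr < 0) | (arr > 1)):
                out.append(f"CSE {name} entries must lie in [0, 1]")
        return out

    def fingerprint(self):
        return (self.times.tobytes(), self.rho.tobytes(), self.q.tobytes())


@dataclass
class BDMSParams:
    """Full BDMS parameter bundle.

    ``lam`` and ``gamma`` are d x d nested sequences of
    :class:`~phylofe.rates.RateFunction`; ``mu``, ``psi``, ``r`` are length-d
    sequences.  ``r`` entries are [0, 1]-valued time functions realized with
    the same rate machinery.  ``n_max`` is the extant-population capacity
    guard (``math.inf`` for unbounded).
    """

    types: TypeSpace
    pi: np.ndarray
    lam: list[list[RateFunction]]
    mu: list[RateFunction]
    gamma: list[list[RateFunction]]
    psi: list[RateFunction]
    r: list[RateFunction]
    cse: CSESchedule
    t_max: float
    n_max: float = math.inf
    name: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __init__(self, types, pi, lam, mu, gamma, psi, r, cse, t_max,
                 n_max=math.inf, name=""):
        if not isinstance(types, TypeSpace):
            types = TypeSpace(types)
        self.types = types
        d = types.d
        self.pi = np.asarray(pi, dtype=float)
        self.lam = [[as_rate(lam[a][b], name=f"lambda[{a}][{b}]") for b in range(d)]
                    for a in range(d)]
        self.gamma = [[as_rate(gamma[a][b], name=f"gamma[{a}][{b}]") for b in range(d)]
                      for a in range(d)]
        self.mu = [as_rate(mu[a], name=f"mu[{a}]") for a in range(d)]
        self.psi = [as_rate(psi[a], name=f"psi[{a}]") for a in range(d)]
        self.r = [as_rate(r[a], name=f"r[{a}]") for a in range(d)]
        if not isinstance(cse, CSESchedule):
            raise TypeError("cse must be a CSESchedule")
        self.cse = cse
        self.t_max = float(t_max)
        self.n_max = math.inf if n_max in (None, "inf") else float(n_max)
        self.name = name
        self._cache = {}

    @property
    def d(self) -> int:
        return self.types.d

    # -- helpers used throughout the simulators ---------------------------

    def is_time_homogeneous(self) -> bool:
        """True when every rate is a plain constant (fast simulation path)."""
        key = "homog"
        if key not in self._cache:
            rf = self._all_rates()
            self._cache[key] = all(isinstance(f, ConstantRate) for f in rf)
        return self._cache[key]

    def is_piecewise_constant(self) -> bool:
        key = "pw"
        if key not in self._cache:
            self._cache[key] = all(f.is_piecewise_constant for f in self._all_rates())
        return self._cache[key]

    def _all_rates(self):
        out = []
        for a in range(self.d):
            out.extend(self.lam[a])
            out.extend(self.gamma[a])
            out.append(self.mu[a])
            out.append(self.psi[a])
        return out

    def per_capita_rate(self, a: int, tau):
        """Total event intensity of one extant type-``a`` lineage at ``tau``."""
        tot = self.mu[a].value_at(tau) + self.psi[a].value_at(tau)
        for b in range(self.d):
            tot += self.lam[a][b].value_at(tau) + self.gamma[a][b].value_at(tau)
        return tot

    def per_capita_upper_bound(self, a: int, lo: float, hi: float) -> float:
        tot = self.mu[a].upper_bound_on(lo, hi) + self.psi[a].upper_bound_on(lo, hi)
        for b in range(self.d):
            tot += self.lam[a][b].upper_bound_on(lo, hi)
            tot += self.gamma[a][b].upper_bound_on(lo, hi)
        return tot

    def jump_points(self, lo: float, hi: float) -> list[float]:
        pts: set[float] = set()
        for f in self._all_rates():
            pts.update(f.jump_points(lo, hi))
        return sorted(pts)

    def fingerprint(self):
        return (
            self.types.labels,
            self.pi.tobytes(),
            tuple(f.fingerprint() for f in self._all_rates()),
            tuple(f.fingerprint() for f in self.r),
            self.cse.fingerprint(),
            self.t_max,
            self.n_max,
        )


def validate_params(theta: BDMSParams, *, check_grid: int = 257) -> list[str]:
    """Return a list of invariant-violation descriptions (empty iff valid).

    Rate nonnegativity and r in [0,1] are checked on a uniform time grid of
    ``check_grid`` points plus all declared jump points.
    """
    out: list[str] = []
    out.extend(theta.types.violations())
    d = theta.d

    if theta.pi.shape != (d,):
        out.append(f"pi must have length d={d}, got shape {theta.pi.shape}")
    else:
        if np.any(theta.pi < 0):
            out.append("pi entries must be nonnegative")
        if abs(theta.pi.sum() - 1.0) > _PROB_TOL:
            out.append(f"pi does not sum to 1 (sum={theta.pi.sum()!r})")

    if not (theta.t_max > 0 and np.isfinite(theta.t_max)):
        out.append(f"t_max must be positive and finite, got {theta.t_max}")
    if not (theta.n_max == math.inf or (theta.n_max == int(theta.n_max) and theta.n_max >= 1)):
        out.append(f"n_max must be a positive integer or inf, got {theta.n_max}")

    taus = np.linspace(0.0, theta.t_max, check_grid)
    extra = theta.jump_points(0.0, theta.t_max)
    if extra:
        taus = np.unique(np.concatenate([taus, extra, np.nextafter(extra, theta.t_max)]))

    def _check_nonneg(f, label):
        v = np.asarray(f.value_at(taus), dtype=float)
        if np.any(v < 0):
            out.append(f"{label} takes a negative value on [0, t_max]")

    for a in range(d):
        la = theta.types.labels[a]
        for b in range(d):
            lb = theta.types.labels[b]
            _check_nonneg(theta.lam[a][b], f"lambda[{la}][{lb}]")
            _check_nonneg(theta.gamma[a][b], f"gamma[{la}][{lb}]")
            if a == b and not theta.gamma[a][a].is_zero():
                va = np.asarray(theta.gamma[a][a].value_at(taus))
                if np.any(va != 0):
                    out.append(f"gamma diagonal cell ({la},{la}) must be identically zero")
        _check_nonneg(theta.mu[a], f"mu[{la}]")
        _check_nonneg(theta.psi[a], f"psi[{la}]")
        rv = np.asarray(theta.r[a].value_at(taus), dtype=float)
        if np.any((rv < 0) | (rv > 1)):
            out.append(f"r[{la}] must take values in [0, 1]")

    out.extend(theta.cse.violations(d, theta.t_max))
    return out


def total_event_rate(theta: BDMSParams, counts, tau: float) -> float:
    """Total Poisson intensity of the extant population at time ``tau``.

    ``sum_a counts[a] * (sum_b lam[a][b] + mu[a] + psi[a] + sum_b gamma[a][b])``
    evaluated at ``tau``; O(d^2) regardless of population size.
    """
    if not (0.0 <= tau <= theta.t_max):
        raise ValueError(f"tau={tau} outside [0, t_max={theta.t_max}]")
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return float(
        sum(counts[a] * theta.per_capita_rate(a, tau) for a in range(theta.d))
    )
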