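"""Breadth-first full-population BDMS simulation.

The simulator advances a single biological clock from ``tau = t_max`` toward
the present, generating one event per iteration anywhere in the tree.  The
cost of each iteration is O(d^2) in the number of types and constant in the
population size: the next event's time and category are drawn from the
superposed Poisson process of the whole extant population, and the lineage it
lands on is drawn uniformly from the per-type extant sets.

Waiting times are sampled exactly by integrated-intensity inversion when all
rates are (piecewise) constant, and by windowed thinning against per-window
upper bounds otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import BDMSParams, validate_params
from .tree import (
    BIRTH, CSE_SAMPLE_DIE, CSE_SAMPLE_SURVIVE, DEATH, MUTATION,
    PRESENT_UNSAMPLED_TIP, ROOT, SAMPLING_DIE, SAMPLING_SURVIVE, Tree,
)

__all__ = ["NextEvent", "ExtantSet", "get_next_event", "simulate_full"]

# Event categories produced by get_next_event.
KIND_BIRTH = "birth"
KIND_DEATH = "death"
KIND_MUTATION = "mutation"
KIND_SAMPLING = "sampling"

#: default thinning window width (time units) for non-piecewise rates
_THINNING_WINDOW = 0.5


@dataclass
class NextEvent:
    """Proposed next event of the superposed population process."""

    tau: float
    kind: str = ""
    parent_type: int = -1
    child_type: int = -1
    none_before: bool = False

    @classmethod
    def nothing(cls, tau_floor: float) -> "NextEvent":
        return cls(tau=tau_floor, none_before=True)


class ExtantSet:
    """Per-type sets of extant lineages with O(1) insert, remove and
    uniform draw (indexable arrays with swap-remove plus a token->position
    map).  Tokens identify lineages; several lineages may share the same
    most-recent event node (the two daughters of a birth)."""

    def __init__(self, d: int):
        self.d = d
        self._lists: list[list[int]] = [[] for _ in range(d)]
        self._pos: dict[int, tuple[int, int]] = {}
        self.node_of: dict[int, int] = {}
        self._next_token = 0

    def insert(self, type_idx: int, node_id: int) -> int:
        token = self._next_token
        self._next_token += 1
        lst = self._lists[type_idx]
        self._pos[token] = (type_idx, len(lst))
        lst.append(token)
        self.node_of[token] = node_id
        return token

    def remove(self, token: int) -> None:
        a, i = self._pos.pop(token)
        lst = self._lists[a]
        last = lst.pop()
        if last != token:
            lst[i] = last
            self._pos[last] = (a, i)
        del self.node_of[token]

    def draw(self, type_idx: int, rng: np.random.Generator) -> int:
        lst = self._lists[type_idx]
        return lst[rng.integers(len(lst))]

    def type_of(self, token: int) -> int:
        return self._pos[token][0]

    def counts(self) -> np.ndarray:
        return np.array([len(lst) for lst in self._lists])

    @property
    def total(self) -> int:
        return len(self._pos)

    def tokens(self) -> list[int]:
        return list(self._pos)


# ---------------------------------------------------------------------------
# next-event sampling
# ---------------------------------------------------------------------------

def _homogeneous_tables(theta: BDMSParams):
    """Per-type constant per-capita totals and channel decompositions."""
    key = "homog_tables"
    if key not in theta._cache:
        d = theta.d
        h = np.empty(d)
        channels = []
        for a in range(d):
            lam = np.array([theta.lam[a][b].value for b in range(d)])
            gam = np.array([theta.gamma[a][b].value for b in range(d)])
            mu = theta.mu[a].value
            psi = theta.psi[a].value
            h[a] = lam.sum() + gam.sum() + mu + psi
            channels.append((lam, mu, psi, gam))
        theta._cache[key] = (h, channels)
    return theta._cache[key]


def _pick_category(theta: BDMSParams, counts, tau: float, rng) -> NextEvent:
    """Two-stage draw of (parent type, event category) proportional to the
    intensity decomposition at a fixed event time ``tau``."""
    d = theta.d
    w = np.array(
        [counts[a] * theta.per_capita_rate(a, tau) if counts[a] else 0.0
         for a in range(d)],
        dtype=float,
    )
    cw = np.cumsum(w)
    a = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
    lam = np.array([theta.lam[a][b].value_at(tau) for b in range(d)])
    gam = np.array([theta.gamma[a][b].value_at(tau) for b in range(d)])
    mu = theta.mu[a].value_at(tau)
    psi = theta.psi[a].value_at(tau)
    weights = np.concatenate([lam, [mu, psi], gam])
    cwk = np.cumsum(weights)
    k = int(np.searchsorted(cwk, rng.random() * cwk[-1], side="right"))
    if k < d:
        return NextEvent(tau=tau, kind=KIND_BIRTH, parent_type=a, child_type=k)
    if k == d:
        return NextEvent(tau=tau, kind=KIND_DEATH, parent_type=a)
    if k == d + 1:
        return NextEvent(tau=tau, kind=KIND_SAMPLING, parent_type=a)
    return NextEvent(tau=tau, kind=KIND_MUTATION, parent_type=a, child_type=k - d - 2)


def get_next_event(theta: BDMSParams, counts, tau_now: float, tau_floor: float,
                   rng: np.random.Generator) -> NextEvent:
    """Sample the first event of the population process on ``(tau_floor, tau_now)``.

    Returns a ``none_before`` event when no event occurs before ``tau_floor``
    (including when the total intensity over the window is zero).  Cost is
    O(d^2) per candidate, independent of the total population size.
    """
    if not tau_floor < tau_now:
        raise ValueError(f"need tau_floor < tau_now, got {tau_floor} >= {tau_now}")
    counts = np.asarray(counts)
    if counts.sum() == 0:
        return NextEvent.nothing(tau_floor)

    if theta.is_time_homogeneous():
        h, _ = _homogeneous_tables(theta)
        rate = float(counts @ h)
        if rate == 0.0:
            return NextEvent.nothing(tau_floor)
        tau_star = tau_now - rng.exponential(1.0 / rate)
        if tau_star <= tau_floor:
            return NextEvent.nothing(tau_floor)
        return _pick_category(theta, counts, tau_star, rng)

    if theta.is_piecewise_constant():
        return _next_event_piecewise(theta, counts, tau_now, tau_floor, rng)
    return _next_event_thinning(theta, counts, tau_now, tau_floor, rng)


def _next_event_piecewise(theta, counts, tau_now, tau_floor, rng) -> NextEvent:
    """Exact inversion of the integrated intensity, segment by segment: the
    exponential deviate is carried across constant-rate pieces."""
    cuts = [tau_floor] + theta.jump_points(tau_floor, tau_now) + [tau_now]
    e = rng.exponential(1.0)
    d = theta.d
    active = [a for a in range(d) if counts[a]]
    # walk segments from tau_now downward
    for lo, hi in zip(reversed(cuts[:-1]), reversed(cuts[1:])):
        mid = 0.5 * (lo + hi)
        rate = sum(counts[a] * theta.per_capita_rate(a, mid) for a in active)
        if rate > 0.0:
            span = hi - lo
            if rate * span >= e:
                tau_star = hi - e / rate
                if tau_star <= tau_floor:
                    return NextEvent.nothing(tau_floor)
                return _pick_category(theta, counts, tau_star, rng)
            e -= rate * span
    return NextEvent.nothing(tau_floor)


def _next_event_thinning(theta, counts, tau_now, tau_floor, rng) -> NextEvent:
    """Windowed thinning: candidates from a homogeneous process at the
    per-window upper bound, accepted with probability intensity/bound."""
    d = theta.d
    active = [a for a in range(d) if counts[a]]
    width = max(_THINNING_WINDOW, (tau_now - tau_floor) / 64.0)
    hi = tau_now
    while hi > tau_floor:
        lo = max(tau_floor, hi - width)
        bound = sum(counts[a] * theta.per_capita_upper_bound(a, lo, hi) for a in active)
        if bound <= 0.0:
            hi = lo
            continue
        t = hi
        while True:
            t -= rng.exponential(1.0 / bound)
            if t <= lo:
                break
            rate = sum(counts[a] * theta.per_capita_rate(a, t) for a in active)
            if rng.random() * bound < rate:
                if t <= tau_floor:
                    return NextEvent.nothing(tau_floor)
                return _pick_category(theta, counts, t, rng)
        hi = lo
    return NextEvent.nothing(tau_floor)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def simulate_full(theta: BDMSParams, rng: np.random.Generator, *,
                  validate: bool = True) -> tuple[Tree, bool]:
    """Simulate the complete population tree forward in biological time.

    Returns ``(tree, capacity_exceeded)``.  The root's type is drawn from
    ``Cat(pi)``; events are generated breadth-first via :func:`get_next_event`
    and land on a uniformly random extant lineage of the drawn type.  When the
    proposed event time crosses a CSE time the event is discarded, all
    lineages advance to the CSE, and per-lineage Bernoulli sampling/death is
    applied; at ``tau = 0`` the present-day CSE runs and unsampled survivors
    become ``present_unsampled_tip`` nodes.  If the extant population exceeds
    ``theta.n_max`` the partial tree is returned with the flag set.
    """
    if validate:
        problems = validate_params(theta)
        if problems:
            raise ValueError("invalid BDMS parameters: " + "; ".join(problems))

    d = theta.d
    tree = Tree(type_labels=theta.types.labels)
    extant = ExtantSet(d)

    root_type = int(rng.choice(d, p=theta.pi))
    root_id = tree.add_node(None, theta.t_max, root_type, ROOT)
    extant.insert(root_type, root_id)

    cse_times = theta.cse.times
    # boundaries strictly below t_max, descending; CSE index alongside
    boundaries = [(cse_times[l], l) for l in range(cse_times.size - 1, -1, -1)
                  if cse_times[l] < theta.t_max]
    # a CSE exactly at t_max applies to the root lineage immediately
    opening = [l for l in range(cse_times.size) if cse_times[l] == theta.t_max]

    tau = theta.t_max
    capacity_exceeded = False

    def apply_cse(l: int, t_l: float) -> None:
        rho = theta.cse.rho[:, l]
        q = theta.cse.q[:, l]
        at_present = t_l == 0.0
        for token in extant.tokens():
            a = extant.type_of(token)
            prev = extant.node_of[token]
            if rng.random() < rho[a]:
                dies = rng.random() < q[a]
                ev = CSE_SAMPLE_DIE if dies else CSE_SAMPLE_SURVIVE
                nid = tree.add_node(prev, t_l, a, ev, edge_type=a)
                if dies or at_present:
                    extant.remove(token)
                else:
                    extant.node_of[token] = nid
            elif at_present:
                tree.add_node(prev, 0.0, a, PRESENT_UNSAMPLED_TIP, edge_type=a)
                extant.remove(token)

    for l in opening:
        apply_cse(l, theta.t_max)

    for t_b, l in boundaries:
        while extant.total:
            ev = get_next_event(theta, extant.counts(), tau, t_b, rng)
            if ev.none_before:
                break
            tau = ev.tau
            a = ev.parent_type
            token = extant.draw(a, rng)
            prev = extant.node_of[token]
            if ev.kind == KIND_BIRTH:
                nid = tree.add_node(prev, tau, a, BIRTH, edge_type=a)
                extant.remove(token)
                extant.insert(a, nid)
                extant.insert(ev.child_type, nid)
            elif ev.kind == KIND_DEATH:
                tree.add_node(prev, tau, a, DEATH, edge_type=a)
                extant.remove(token)
            elif ev.kind == KIND_MUTATION:
                b = ev.child_type
                nid = tree.add_node(prev, tau, b, MUTATION, edge_type=a)
                extant.remove(token)
                extant.insert(b, nid)
            else:  # serial sampling
                dies = rng.random() < theta.r[a].value_at(tau)
                ev_name = SAMPLING_DIE if dies else SAMPLING_SURVIVE
                nid = tree.add_node(prev, tau, a, ev_name, edge_type=a)
                if dies:
                    extant.remove(token)
                else:
                    extant.node_of[token] = nid
            if extant.total > theta.n_max:
                capacity_exceeded = True
                return tree, capacity_exceeded
        if not extant.total:
            break
        tau = t_b
        apply_cse(l, t_b)

    return tree, capacity_exceeded
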