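"""Shared fixtures: reference models, random-model factories, and an
independent brute-force pruning oracle."""

from __future__ import annotations

import numpy as np
import pytest

from phylofe import BDMSParams, CSESchedule, Tree
from phylofe.presets import (
    fig2_two_type_model,
    massive_subsampling_model,
    single_type_model,
    stick_model,
    two_type_validation_model,
)
from phylofe.tree import ROOT, SAMPLING_EVENTS


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def validation_model():
    return two_type_validation_model()


@pytest.fixture
def fig2_model():
    return fig2_two_type_model(rho=0.01)


@pytest.fixture
def massive_model():
    return massive_subsampling_model()


@pytest.fixture
def stick():
    return stick_model(rho=0.5)


@pytest.fixture
def yule():
    return single_type_model(1.0, 0.0, rho=1.0, t_max=1.0)


def random_model(rng: np.random.Generator, *, allow_psi: bool = True,
                 allow_cse: bool = True, max_types: int = 3) -> BDMSParams:
    """A random small BDMS model with modest rates (trees of ~tens of nodes),
    mixing constant and piecewise-constant rates, serial sampling with
    survival, and optionally an intermediate CSE."""
    d = int(rng.integers(1, max_types + 1))
    t_max = float(rng.uniform(0.8, 2.5))

    def rate(scale):
        v = float(rng.uniform(0.0, scale))
        if rng.random() < 0.3:
            bp = sorted(rng.uniform(0.05, t_max - 0.05, size=rng.integers(1, 3)))
            vals = rng.uniform(0.0, scale, size=len(bp) + 1)
            return {"breakpoints": [float(b) for b in bp],
                    "values": [float(x) for x in vals]}
        return v

    lam = [[rate(1.2) if a == b else (rate(0.4) if rng.random() < 0.4 else 0.0)
            for b in range(d)] for a in range(d)]
    gamma = [[0.0 if a == b else (rate(0.6) if rng.random() < 0.7 else 0.0)
              for b in range(d)] for a in range(d)]
    mu = [rate(0.6) for _ in range(d)]
    psi = [rate(0.5) if (allow_psi and rng.random() < 0.6) else 0.0 for _ in range(d)]
    r = [float(rng.uniform(0, 1)) for _ in range(d)]
    pi = rng.dirichlet(np.ones(d))

    times = [0.0]
    rho = [[float(rng.uniform(0.2, 1.0))] for _ in range(d)]
    q = [[float(rng.uniform(0, 1))] for _ in range(d)]
    if allow_cse and rng.random() < 0.5:
        times.append(float(rng.uniform(0.1, t_max * 0.9)))
        for a in range(d):
            rho[a].append(float(rng.uniform(0.0, 0.6)))
            q[a].append(float(rng.uniform(0, 1)))
    return BDMSParams(
        types=[f"T{i}" for i in range(d)], pi=pi, lam=lam, mu=mu, gamma=gamma,
        psi=psi, r=r, cse=CSESchedule(times=times, rho=rho, q=q), t_max=t_max,
    )


def oracle_prune(tree: Tree) -> Tree:
    """Quadratic reference pruning: for every node, exhaustively search its
    descendant set for sampling events, then rebuild recursively."""
    if tree.is_empty:
        return Tree.empty(tree.type_labels)

    def descendants_sampled(nid) -> bool:
        node = tree[nid]
        if node.event in SAMPLING_EVENTS:
            return True
        return any(descendants_sampled(c) for c in node.children)

    if not descendants_sampled(tree.root):
        return Tree.empty(tree.type_labels)

    out = Tree(type_labels=tree.type_labels, is_reconstructed=True)

    def rebuild(nid, parent_out):
        node = tree[nid]
        kept = [c for c in node.children if descendants_sampled(c)]
        if node.event == "birth" and len(kept) == 1:
            daughter = tree[kept[0]].edge_type
            if daughter == node.type:
                rebuild(kept[0], parent_out)
                return
            new_id = out.add_node(parent_out, node.time, daughter, "mutation",
                                  edge_type=node.edge_type, id=node.id)
            rebuild(kept[0], new_id)
            return
        new_id = out.add_node(parent_out, node.time, node.type, node.event,
                              edge_type=node.edge_type, id=node.id)
        for c in kept:
            rebuild(c, new_id)

    root = tree[tree.root]
    out.add_node(None, root.time, root.type, ROOT, id=root.id)
    for c in root.children:
        if descendants_sampled(c):
            rebuild(c, root.id)
    return out


def tree_signature(tree: Tree):
    """Canonical node-for-node description for equality checks."""
    if tree.is_empty:
        return "EMPTY"
    return sorted(
        (n.id, n.parent, round(n.time, 12), n.type, n.edge_type, n.event,
         tuple(sorted(n.children)))
        for n in tree.nodes.values()
    )


def max_width(tree: Tree) -> int:
    """Maximal number of simultaneously extant lineages in a tree, from a
    sweep over its edges (an edge spans (child.time, parent.time])."""
    if tree.is_empty:
        return 0
    deltas = []
    for n in tree.nodes.values():
        if n.parent is None:
            continue
        parent_t = tree[n.parent].time
        deltas.append((parent_t, 1))
        deltas.append((n.time, -1))
    # sweep tau downward; at equal tau, ends (-1) before starts to keep the
    # half-open convention
    deltas.sort(key=lambda x: (-x[0], x[1]))
    cur = best = 0
    for _, dlt in deltas:
        cur += dlt
        best = max(best, cur)
    return best
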