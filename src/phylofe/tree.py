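"""Rooted trees of timed, typed event nodes.

Nodes record the simulation events (birth, death, anagenetic mutation, serial
sampling, concerted sampling, present-day unsampled tips) plus a ``root``
marker for the stem origin at ``tau = t_max``.  Time decreases from the root
toward the present; every branch length is ``parent.time - child.time``.

The empty reconstructed tree (all lineages extinct or unsampled) is an
explicit sentinel, :meth:`Tree.empty`, with ``root is None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "EventNode",
    "Tree",
    "ROOT", "BIRTH", "DEATH", "MUTATION",
    "SAMPLING_SURVIVE", "SAMPLING_DIE",
    "CSE_SAMPLE_SURVIVE", "CSE_SAMPLE_DIE",
    "PRESENT_UNSAMPLED_TIP",
    "SAMPLING_EVENTS", "TERMINAL_EVENTS", "EVENT_KINDS",
]

ROOT = "root"
BIRTH = "birth"
DEATH = "death"
MUTATION = "mutation"
SAMPLING_SURVIVE = "sampling_survive"
SAMPLING_DIE = "sampling_die"
CSE_SAMPLE_SURVIVE = "cse_sample_survive"
CSE_SAMPLE_DIE = "cse_sample_die"
PRESENT_UNSAMPLED_TIP = "present_unsampled_tip"

#: Events that constitute an observation of the lineage.
SAMPLING_EVENTS = frozenset(
    {SAMPLING_SURVIVE, SAMPLING_DIE, CSE_SAMPLE_SURVIVE, CSE_SAMPLE_DIE}
)
#: Events after which the lineage no longer exists.
TERMINAL_EVENTS = frozenset({DEATH, SAMPLING_DIE, CSE_SAMPLE_DIE, PRESENT_UNSAMPLED_TIP})
EVENT_KINDS = frozenset(
    {ROOT, BIRTH, DEATH, MUTATION, SAMPLING_SURVIVE, SAMPLING_DIE,
     CSE_SAMPLE_SURVIVE, CSE_SAMPLE_DIE, PRESENT_UNSAMPLED_TIP}
)

_MAX_CHILDREN = {
    ROOT: 1, BIRTH: 2, MUTATION: 1,
    SAMPLING_SURVIVE: 1, CSE_SAMPLE_SURVIVE: 1,
    DEATH: 0, SAMPLING_DIE: 0, CSE_SAMPLE_DIE: 0, PRESENT_UNSAMPLED_TIP: 0,
}


@dataclass
class EventNode:
    """One timed, typed event.

    ``type`` is the lineage's type *at and after* this node; ``edge_type`` is
    its type along the incoming edge (they differ only at anagenetic-mutation
    nodes, where ``edge_type`` is the pre-mutation type, and at birth nodes
    whose incoming edge carries the parent lineage's type).
    """

    id: int
    parent: int | None
    time: float
    type: int
    event: str
    edge_type: int = -1
    children: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.edge_type < 0:
            self.edge_type = self.type


class Tree:
    """Id-indexed collection of :class:`EventNode` with a single root."""

    def __init__(self, type_labels=(), is_reconstructed: bool = False):
        self.nodes: dict[int, EventNode] = {}
        self.root: int | None = None
        self.type_labels = tuple(type_labels)
        self.is_reconstructed = is_reconstructed
        self._next_id = 0

    # -- construction ------------------------------------------------------

    @classmethod
    def empty(cls, type_labels=()) -> "Tree":
        """The empty-tree sentinel: pruning left nothing."""
        return cls(type_labels=type_labels, is_reconstructed=True)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def add_node(self, parent: int | None, time: float, type: int, event: str,
                 edge_type: int | None = None, id: int | None = None) -> int:
        nid = self._next_id if id is None else id
        self._next_id = max(self._next_id, nid + 1)
        node = EventNode(
            id=nid, parent=parent, time=float(time), type=int(type), event=event,
            edge_type=int(type) if edge_type is None else int(edge_type),
        )
        if nid in self.nodes:
            raise ValueError(f"duplicate node id {nid}")
        self.nodes[nid] = node
        if parent is None:
            if self.root is not None:
                raise ValueError("tree already has a root")
            self.root = nid
        else:
            self.nodes[parent].children.append(nid)
        return nid

    # -- traversal ---------------------------------------------------------

    def __len__(self):
        return len(self.nodes)

    def __getitem__(self, nid: int) -> EventNode:
        return self.nodes[nid]

    def preorder(self):
        if self.is_empty:
            return
        stack = [self.root]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        if self.is_empty:
            return
        stack = [(self.root, False)]
        while stack:
            nid, done = stack.pop()
            if done:
                yield self.nodes[nid]
            else:
                stack.append((nid, True))
                for c in self.nodes[nid].children:
                    stack.append((c, False))

    def leaves(self):
        return [n for n in self.nodes.values() if not n.children]

    def branch_length(self, nid: int) -> float:
        node = self.nodes[nid]
        if node.parent is None:
            return 0.0
        return self.nodes[node.parent].time - node.time

    def total_branch_length(self) -> float:
        return sum(self.branch_length(n.id) for n in self.nodes.values())

    def label_of(self, type_index: int) -> str:
        if self.type_labels:
            return self.type_labels[type_index]
        return str(type_index)

    # -- invariants ---------------------------------------------------------

    def check(self) -> list[str]:
        """Structural-invariant violations (empty list iff the tree is valid)."""
        out: list[str] = []
        if self.is_empty:
            if self.nodes:
                out.append("empty tree must contain no nodes")
            return out
        seen = set()
        for node in self.preorder():
            if node.id in seen:
                out.append(f"node {node.id} reachable twice (cycle or shared child)")
                break
            seen.add(node.id)
            if node.event not in EVENT_KINDS:
                out.append(f"node {node.id}: unknown event {node.event!r}")
                continue
            if len(node.children) > _MAX_CHILDREN[node.event]:
                out.append(
                    f"node {node.id} ({node.event}) has {len(node.children)} children "
                    f"(max {_MAX_CHILDREN[node.event]})"
                )
            if node.parent is not None:
                pt = self.nodes[node.parent].time
                if node.time > pt + 1e-12:
                    out.append(f"node {node.id} time {node.time} exceeds parent time {pt}")
        if len(seen) != len(self.nodes):
            out.append(f"{len(self.nodes) - len(seen)} nodes unreachable from the root")
        if self.is_reconstructed:
            for node in self.nodes.values():
                if node.event in (DEATH, PRESENT_UNSAMPLED_TIP):
                    out.append(f"reconstructed tree contains {node.event} node {node.id}")
                if not node.children and node.event not in SAMPLING_EVENTS:
                    out.append(
                        f"reconstructed-tree leaf {node.id} is {node.event}, not a sampling event"
                    )
        return out

    def __repr__(self):
        if self.is_empty:
            return "Tree(EMPTY)"
        kind = "reconstructed" if self.is_reconstructed else "full"
        return f"Tree({kind}, {len(self.nodes)} nodes, root at tau={self.nodes[self.root].time})"
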