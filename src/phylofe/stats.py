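"""Scalar and stratified summary statistics of reconstructed phylogenies.

Statistics follow the validation battery used for distributional-equivalence
testing: event count, leaf count, per-type and total branch length,
subtree-size counts, lineage counts at time cross-sections, and *block*
statistics.  A block is a maximal connected subtree of uniform type; blocks
partition the tree's edges, each non-root node being assigned to the block of
its incoming edge (so an anagenetic-mutation node belongs to its parent-side,
pre-mutation block, and a birth node to its parent-type block).

Cross-section convention: an edge from parent time ``tau_p`` to child time
``tau_c`` contributes one lineage at time ``tau`` iff ``tau_c < tau <= tau_p``
(half-open toward the present, so counts are right-continuous in ``tau``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .tree import ROOT, Tree

__all__ = ["TreeStatSet", "Block", "summary_stats", "block_decomposition"]


@dataclass
class TreeStatSet:
    """Summary statistics of one reconstructed tree.  The stem-origin marker
    at the root is not an event and is excluded from all node counts."""

    event_count: int = 0
    leaf_count: int = 0
    branch_length_total: float = 0.0
    branch_length_by_type: dict[str, float] = field(default_factory=dict)
    #: number of nodes whose descendant subtree (node included) has k nodes
    subtree_sizes: Counter = field(default_factory=Counter)
    #: (type label, tau) -> lineage count at the cross-section
    lineage_counts: dict[tuple[str, float], int] = field(default_factory=dict)
    is_empty: bool = False


@dataclass
class Block:
    """Maximal connected same-type subtree."""

    type: str
    member_ids: list[int] = field(default_factory=list)
    total_branch_length: float = 0.0
    event_count: int = 0


def summary_stats(tree: Tree, cross_sections: tuple[float, ...] = ()) -> TreeStatSet:
    """Summary statistics of a reconstructed tree; ``cross_sections`` are
    times-before-present at which per-type lineage counts are taken.  The
    EMPTY tree yields all-zero statistics with the emptiness flag set."""
    labels = [tree.label_of(i) for i in range(max(len(tree.type_labels), 1))] \
        if tree.type_labels else None
    if tree.is_empty:
        out = TreeStatSet(is_empty=True)
        if labels:
            out.branch_length_by_type = {lb: 0.0 for lb in labels}
            out.lineage_counts = {(lb, t): 0 for lb in labels for t in cross_sections}
        return out

    out = TreeStatSet()
    if labels:
        out.branch_length_by_type = {lb: 0.0 for lb in labels}
        out.lineage_counts = {(lb, t): 0 for lb in labels for t in cross_sections}
    sizes: dict[int, int] = {}
    for node in tree.postorder():
        sizes[node.id] = 1 + sum(sizes[c] for c in node.children)
        if node.event == ROOT:
            continue
        out.event_count += 1
        out.subtree_sizes[sizes[node.id]] += 1
        if not node.children:
            out.leaf_count += 1
        tau_p = tree[node.parent].time
        length = tau_p - node.time
        lb = tree.label_of(node.edge_type)
        out.branch_length_total += length
        out.branch_length_by_type[lb] = out.branch_length_by_type.get(lb, 0.0) + length
        for t in cross_sections:
            if node.time < t <= tau_p:
                key = (lb, t)
                out.lineage_counts[key] = out.lineage_counts.get(key, 0) + 1
    return out


def block_decomposition(tree: Tree) -> list[Block]:
    """Partition the tree's edges into maximal connected same-type blocks.

    Two edges belong to the same block iff they are adjacent (one's child
    node is the other's parent node) and carry the same type.  Each non-root
    node is assigned to the block of its incoming edge, so the per-block
    event counts sum to the tree's event count and the per-block branch
    lengths sum to the total branch length.
    """
    if tree.is_empty:
        return []
    blocks: list[Block] = []
    # block id per node (keyed by node id; the node represents its incoming edge)
    assignment: dict[int, int] = {}
    for node in tree.preorder():
        if node.event == ROOT:
            continue
        parent = tree[node.parent]
        if parent.event != ROOT and parent.edge_type == node.edge_type:
            bid = assignment[parent.id]
        else:
            bid = len(blocks)
            blocks.append(Block(type=tree.label_of(node.edge_type)))
        assignment[node.id] = bid
        blk = blocks[bid]
        blk.member_ids.append(node.id)
        blk.event_count += 1
        blk.total_branch_length += parent.time - node.time
    return blocks
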