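"""Pruning: extract the reconstructed phylogeny from a full population tree.

A node survives pruning iff it is ancestral to (or is itself) a sampling
event.  Birth nodes left with a single surviving daughter are dissolved when
the daughter lineage has the parent's type, and turned into anagenetic
mutation nodes when it does not (a cladogenetic type change whose same-type
daughter went unobserved is indistinguishable from an anagenetic mutation).
Serial-sampling nodes that survive sampling are kept as unary internal nodes;
if their continuation has no sampled descendants it is truncated and the
sampling node becomes a leaf.  The stem origin at ``tau = t_max`` is kept as
the root of the reconstructed tree.

Runs in time linear in the number of nodes of the input tree.
"""

from __future__ import annotations

from .tree import BIRTH, MUTATION, ROOT, SAMPLING_EVENTS, Tree

__all__ = ["prune"]


def prune(tree: Tree) -> Tree:
    """Reconstructed phylogeny of a full-simulation tree (possibly EMPTY)."""
    if tree.is_reconstructed:
        raise ValueError("input tree is already reconstructed; prune expects a full tree")
    return _prune_unchecked(tree)


def _prune_unchecked(tree: Tree) -> Tree:
    """Pruning rules without the is_reconstructed usage guard (re-running them
    on an already-reconstructed tree must be the identity; tested)."""
    if tree.is_empty:
        return Tree.empty(tree.type_labels)

    # postorder: kept iff sampling event or any kept child
    kept: dict[int, bool] = {}
    for node in tree.postorder():
        kept[node.id] = node.event in SAMPLING_EVENTS or any(
            kept[c] for c in node.children
        )

    if not kept[tree.root]:
        return Tree.empty(tree.type_labels)

    out = Tree(type_labels=tree.type_labels, is_reconstructed=True)
    # stack of (node_id_in_full, parent_id_in_out)
    root = tree[tree.root]
    out.add_node(None, root.time, root.type, ROOT, id=root.id)
    stack = [(c, root.id) for c in root.children if kept[c]]
    while stack:
        nid, new_parent = stack.pop()
        node = tree[nid]
        kept_children = [c for c in node.children if kept[c]]
        if node.event == BIRTH and len(kept_children) == 1:
            child = kept_children[0]
            daughter_type = tree[child].edge_type
            if daughter_type == node.type:
                # invisible birth: dissolve the node, merging the two edges
                stack.append((child, new_parent))
            else:
                # surviving daughter changed type: appears as an anagenetic mutation
                out.add_node(new_parent, node.time, daughter_type, MUTATION,
                             edge_type=node.edge_type, id=node.id)
                stack.append((child, node.id))
        else:
            out.add_node(new_parent, node.time, node.type, node.event,
                         edge_type=node.edge_type, id=node.id)
            for c in kept_children:
                stack.append((c, node.id))
    return out
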