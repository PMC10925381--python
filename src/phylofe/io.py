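"""Tree and table serialization, and the model-config loader.

Trees are written as Newick with per-node NHX-style annotations carrying
``{id, event, type, edge type, time}``; unary nodes (anagenetic mutations,
sampled ancestors) are serialized as unifurcations.  A companion TSV event
table (node_id, parent_id, time, type, event, edge_type) is written
alongside.  The EMPTY reconstructed tree is a sentinel file containing the
literal token ``T_EMPTY;``.

Model configs are JSON or TOML with the fixed schema::

    types   list of type-name strings
    pi      list of d probabilities
    lambda  d x d nested lists; each cell a number, {breakpoints, values}
            or {times, values}
    gamma   d x d nested lists, zero diagonal; same cell forms
    mu, psi, r   d lists of the same cell forms
    cse     list of {time, rho: list, q: list}; must include time 0
    t_max   number;  n_max  integer or "inf";  seed  integer (optional)

Unknown keys are rejected.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import dendropy
import pandas as pd

from .params import BDMSParams, CSESchedule, validate_params
from .tree import EVENT_KINDS, Tree

__all__ = ["write_tree", "read_tree", "load_config", "ParseError",
           "EMPTY_SENTINEL"]

EMPTY_SENTINEL = "T_EMPTY;"
_NHX_KEYS = {"id", "ev", "ty", "et", "t", "labels", "rec"}


class ParseError(ValueError):
    """Malformed tree file or config."""


def _events_path(newick_path) -> Path:
    p = Path(newick_path)
    return p.with_suffix(".events.tsv")


def _fmt(x: float) -> str:
    return repr(float(x))


def events_table(tree: Tree) -> pd.DataFrame:
    rows = [
        {
            "node_id": n.id,
            "parent_id": -1 if n.parent is None else n.parent,
            "time": n.time,
            "type": tree.label_of(n.type),
            "event": n.event,
            "edge_type": tree.label_of(n.edge_type),
        }
        for n in tree.preorder()
    ]
    return pd.DataFrame(rows, columns=["node_id", "parent_id", "time", "type",
                                       "event", "edge_type"])


def write_tree(tree: Tree, path, *, collapse_unary: bool = False) -> None:
    """Write ``tree`` as annotated Newick at ``path`` plus a companion
    ``.events.tsv`` event table.  ``collapse_unary`` merges unifurcations
    (mutations, sampled ancestors) into their child edge for tools that
    reject them, moving the annotation onto a comment of the child edge."""
    path = Path(path)
    if tree.is_empty:
        path.write_text(EMPTY_SENTINEL + "\n")
        events_table(tree).to_csv(_events_path(path), sep="\t", index=False)
        return
    problems = tree.check()
    if problems:
        raise ValueError("refusing to serialize an invalid tree: " + "; ".join(problems))

    def annot(n, extra=""):
        parts = [f"id={n.id}", f"ev={n.event}", f"ty={tree.label_of(n.type)}"]
        if n.edge_type != n.type:
            parts.append(f"et={tree.label_of(n.edge_type)}")
        parts.append(f"t={_fmt(n.time)}")
        return "[&&NHX:" + ":".join(parts) + extra + "]"

    def render(nid) -> str:
        n = tree[nid]
        children = n.children
        if collapse_unary:
            while len(children) == 1 and len(tree[children[0]].children) == 1:
                children = tree[children[0]].children  # pragma: no cover
        inner = ""
        if children:
            inner = "(" + ",".join(render(c) for c in children) + ")"
        length = 0.0 if n.parent is None else tree[n.parent].time - n.time
        return f"{inner}n{n.id}:{_fmt(length)}{annot(n)}"

    root = tree[tree.root]
    labels = "|".join(tree.type_labels) if tree.type_labels else ""
    extra = f":labels={labels}:rec={int(tree.is_reconstructed)}"
    # root rendered with the provenance annotation appended
    n = root
    inner = "(" + ",".join(render(c) for c in n.children) + ")" if n.children else ""
    text = f"{inner}n{n.id}:0.0{annot(n, extra)};"
    path.write_text(text + "\n")
    events_table(tree).to_csv(_events_path(path), sep="\t", index=False)


def read_tree(path) -> Tree:
    """Read an annotated Newick file written by :func:`write_tree`.

    Round-trips topology and annotations exactly and node times to full
    float precision.  Malformed Newick or unknown annotation keys raise
    :class:`ParseError` (with the reader's line/column position when the
    Newick itself is malformed)."""
    path = Path(path)
    text = path.read_text()
    if text.strip() == EMPTY_SENTINEL:
        return Tree.empty()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ParseError(f"{path}: malformed Newick: {exc}") from exc

    seed = dtree.seed_node
    root_ann = seed.annotations.values_as_dict()
    unknown = set(root_ann) - _NHX_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown annotation keys {sorted(unknown)}")
    labels = tuple(root_ann.get("labels", "").split("|")) if root_ann.get("labels") else ()
    tree = Tree(type_labels=labels,
                is_reconstructed=bool(int(root_ann.get("rec", "0"))))

    def type_index(label: str) -> int:
        if labels:
            try:
                return labels.index(label)
            except ValueError:
                raise ParseError(f"{path}: unknown type label {label!r}") from None
        return int(label)

    def convert(dnode, parent_id):
        ann = dnode.annotations.values_as_dict()
        unknown = set(ann) - _NHX_KEYS
        if unknown:
            raise ParseError(f"{path}: unknown annotation keys {sorted(unknown)}")
        for req in ("id", "ev", "ty", "t"):
            if req not in ann:
                raise ParseError(f"{path}: node missing annotation {req!r}")
        if ann["ev"] not in EVENT_KINDS:
            raise ParseError(f"{path}: unknown event kind {ann['ev']!r}")
        ty = type_index(ann["ty"])
        et = type_index(ann["et"]) if "et" in ann else ty
        nid = tree.add_node(parent_id, float(ann["t"]), ty, ann["ev"],
                            edge_type=et, id=int(ann["id"]))
        for child in dnode.child_nodes():
            convert(child, nid)

    convert(seed, None)
    problems = tree.check()
    if problems:
        raise ParseError(f"{path}: invalid tree: " + "; ".join(problems))
    return tree


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

_TOP_KEYS = {"types", "pi", "lambda", "gamma", "mu", "psi", "r", "cse",
             "t_max", "n_max", "seed", "name"}
_REQUIRED = {"types", "pi", "lambda", "gamma", "mu", "psi", "r", "cse", "t_max"}


def load_config(path) -> tuple[BDMSParams, int | None]:
    """Parse a JSON/TOML model config into a validated :class:`BDMSParams`.

    Returns ``(theta, seed)`` with ``seed`` None when absent.  Fails fast
    listing *all* schema and invariant violations.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = _REQUIRED - set(raw)
    if missing:
        raise ParseError(f"{path}: missing required config keys {sorted(missing)}")

    cse_raw = raw["cse"]
    if (not isinstance(cse_raw, list) or
            not all(isinstance(e, dict) and set(e) == {"time", "rho", "q"}
                    for e in cse_raw)):
        raise ParseError(f"{path}: cse must be a list of {{time, rho, q}} mappings")
    order = sorted(range(len(cse_raw)), key=lambda i: cse_raw[i]["time"])
    times = [cse_raw[i]["time"] for i in order]
    rho = [[cse_raw[i]["rho"][a] for i in order] for a in range(len(raw["types"]))]
    q = [[cse_raw[i]["q"][a] for i in order] for a in range(len(raw["types"]))]

    try:
        theta = BDMSParams(
            types=raw["types"], pi=raw["pi"], lam=raw["lambda"], mu=raw["mu"],
            gamma=raw["gamma"], psi=raw["psi"], r=raw["r"],
            cse=CSESchedule(times=times, rho=rho, q=q),
            t_max=raw["t_max"], n_max=raw.get("n_max", "inf"),
            name=raw.get("name", path.stem),
        )
    except (ValueError, TypeError, IndexError, KeyError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    problems = validate_params(theta)
    if problems:
        raise ParseError(f"{path}: invalid model: " + "; ".join(problems))
    seed = raw.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise ParseError(f"{path}: seed must be an integer")
    return theta, seed
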