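"""Lineage-tree serialization: structured JSON and annotated Newick.

The JSON document stores one record per node.  The Newick form encodes
the topology with node labels equal to cell ids, branch lengths equal to
node lifetimes, and the remaining node attributes in ``[&key=value]``
comment annotations (parsed back via dendropy).  Both forms round-trip
to equal :class:`~icount.synthetic_data.LineageTree` objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy

from ..synthetic_data import LabelState, LineageNode, LineageTree

__all__ = [
    "tree_to_records",
    "tree_from_records",
    "write_tree_json",
    "read_tree_json",
    "write_tree_newick",
    "read_tree_newick",
    "read_lineage_tree",
]

_FORMAT = "icount-lineage"
_VERSION = 1


def tree_to_records(tree: LineageTree) -> list[dict]:
    records = []
    for node in tree:
        records.append(
            {
                "cell_id": node.cell_id,
                "parent_id": node.parent_id,
                "birth_time": node.birth_time,
                "division_time": node.division_time,
                "fate": node.fate,
                "true_divisions": node.true_divisions,
                "recombined": node.recombined,
                "label": {
                    "red": node.label.red,
                    "green": node.label.green,
                    "blue": node.label.blue,
                },
            }
        )
    return records


def tree_from_records(records: list[dict]) -> LineageTree:
    tree = LineageTree()
    pending = list(records)
    # Insert parents before children regardless of record order.
    inserted: set[str | None] = {None}
    while pending:
        progress = False
        remaining = []
        for rec in pending:
            if rec["parent_id"] in inserted:
                label = rec["label"]
                tree.add(
                    LineageNode(
                        cell_id=str(rec["cell_id"]),
                        parent_id=rec["parent_id"],
                        birth_time=float(rec["birth_time"]),
                        division_time=(
                            None
                            if rec["division_time"] is None
                            else float(rec["division_time"])
                        ),
                        fate=rec["fate"],
                        true_divisions=int(rec["true_divisions"]),
                        recombined=bool(rec["recombined"]),
                        label=LabelState(
                            float(label["red"]),
                            float(label["green"]),
                            float(label["blue"]),
                        ),
                    )
                )
                inserted.add(str(rec["cell_id"]))
                progress = True
            else:
                remaining.append(rec)
        if not progress:
            orphans = sorted(str(r["cell_id"]) for r in remaining)[:5]
            raise ValueError(
                f"orphaned or cyclic node references (e.g. {orphans})"
            )
        pending = remaining
    tree.validate()
    return tree


def write_tree_json(tree: LineageTree, path) -> None:
    doc = {"format": _FORMAT, "version": _VERSION, "nodes": tree_to_records(tree)}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_tree_json(path) -> LineageTree:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not an {_FORMAT} document")
    return tree_from_records(doc["nodes"])


def _node_comment(node: LineageNode) -> str:
    items = {
        "birth": repr(node.birth_time),
        "division": "NA" if node.division_time is None else repr(node.division_time),
        "fate": node.fate,
        "k": str(node.true_divisions),
        "recombined": str(int(node.recombined)),
        "red": repr(node.label.red),
        "green": repr(node.label.green),
        "blue": repr(node.label.blue),
    }
    return "[&" + ",".join(f"{k}={v}" for k, v in items.items()) + "]"


def _newick_subtree(tree: LineageTree, node: LineageNode) -> str:
    children = tree.children(node.cell_id)
    end = node.division_time if node.division_time is not None else node.birth_time
    length = max(end - node.birth_time, 0.0)
    inner = ""
    if children:
        inner = "(" + ",".join(_newick_subtree(tree, c) for c in children) + ")"
    return f"{inner}{node.cell_id}{_node_comment(node)}:{length!r}"


def write_tree_newick(tree: LineageTree, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for root_id in tree.roots:
            fh.write(f"({_newick_subtree(tree, tree.node(root_id))});\n")


def read_tree_newick(path) -> LineageTree:
    trees = dendropy.TreeList.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=False,
        extract_comment_metadata=True,
    )
    records: list[dict] = []
    for dtree in trees:
        for dnode in dtree.preorder_node_iter():
            if dnode.taxon is None:  # synthetic outer root from "(...)" wrapping
                continue
            meta = {a.name: a.value for a in dnode.annotations}
            parent = dnode.parent_node
            parent_id = (
                parent.taxon.label
                if parent is not None and parent.taxon is not None
                else None
            )
            division = meta["division"]
            records.append(
                {
                    "cell_id": dnode.taxon.label,
                    "parent_id": parent_id,
                    "birth_time": float(meta["birth"]),
                    "division_time": None if division == "NA" else float(division),
                    "fate": meta["fate"],
                    "true_divisions": int(meta["k"]),
                    "recombined": bool(int(meta["recombined"])),
                    "label": {
                        "red": float(meta["red"]),
                        "green": float(meta["green"]),
                        "blue": float(meta["blue"]),
                    },
                }
            )
    return tree_from_records(records)


def read_lineage_tree(path) -> LineageTree:
    """Read a lineage tree from JSON or annotated Newick, by extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".nwk", ".newick", ".tre", ".tree"):
        return read_tree_newick(path)
    return read_tree_json(path)
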