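"""Relative evolutionary distance (RED) and rank assignment on rooted trees.

RED normalizes node depth on a rooted tree to [0, 1]: the root is 0, every
extant leaf is 1 by convention, and an internal node n with parent p is

    RED(n) = RED(p) + (d / u) * (1 - RED(p))

where d is the branch length p -> n and u is the mean path length from p to
all of p's leaf descendants. Branch-length scale cancels (d and u scale
together), so RED depends only on relative depths. Internal nodes whose RED
falls inside a rank's interval are labeled with that rank; when an ancestor
and a descendant both land in one rank's interval, the node closer to the
interval midpoint keeps the label by default (a "highest node wins" rule is
also available).

Trees must arrive rooted; no rerooting or averaging over rootings is done.
Parsing and serialization go through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import NewickParseError, ValidationError

#: Default RED windows used when no reference labeling is available.
DEFAULT_RANK_INTERVALS: dict[str, tuple[float, float]] = {
    "family": (0.25, 0.55),
    "genus": (0.65, 0.90),
}


def _ensure_node_ids(tree: dendropy.Tree) -> None:
    """Give every node a unique string id: leaf taxon labels, else node labels,
    else 'n<i>' in preorder. Stored as ``node.node_id``."""
    seen: set[str] = set()
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() and node.taxon is not None:
            nid = node.taxon.label
        elif node.label:
            nid = node.label
        else:
            nid = f"n{counter}"
            counter += 1
        if nid in seen:
            raise ValidationError(f"duplicate node id {nid!r} in tree")
        seen.add(nid)
        node.node_id = nid


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths.

    Unbalanced parentheses or missing branch lengths on non-root edges are
    parse errors.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"invalid Newick: {exc}") from None
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise NewickParseError(
                f"missing branch length on edge to {node.taxon.label if node.taxon else node.label or 'internal node'}"
            )
        if node.edge.length < 0:
            raise ValidationError("negative branch length")
    if sum(1 for _ in tree.leaf_node_iter()) < 1:
        raise NewickParseError("tree has no leaves")
    _ensure_node_ids(tree)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with enough precision that parse(write(t)) round-trips to 1e-9."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
        unquoted_underscores=True,
    ).strip()
    return text if text.endswith(";") else text + ";"


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


@dataclass(frozen=True)
class REDTable:
    """node id -> RED value; root 0, leaves 1, non-decreasing toward the tips."""

    values: dict[str, float]

    def __getitem__(self, node_id: str) -> float:
        return self.values[node_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.values.items()), columns=["node_id", "red"]
        )


def compute_red(tree: dendropy.Tree) -> REDTable:
    """RED for every node of a rooted tree with branch lengths.

    Also caches the value on each node as ``node.red``. Raises when a
    subtree has all-zero branch lengths (u = 0 makes the ratio undefined).
    """
    leaves = [n for n in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValidationError("RED needs a tree with at least 2 leaves")
    if not hasattr(tree.seed_node, "node_id"):
        _ensure_node_ids(tree)
    # postorder: mean root-ward path length from each node to its descendant leaves
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._n_leaves = 1
            node._mean_leaf_dist = 0.0
        else:
            total = 0.0
            count = 0
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                total += child._n_leaves * (child._mean_leaf_dist + bl)
                count += child._n_leaves
            node._n_leaves = count
            node._mean_leaf_dist = total / count
    values: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            red = 0.0
        elif node.is_leaf():
            red = 1.0
        else:
            parent = node.parent_node
            u = parent._mean_leaf_dist
            if u <= 0:
                raise ValidationError(
                    f"degenerate branch lengths: zero mean leaf distance under {parent.node_id!r}"
                )
            d = node.edge.length or 0.0
            red = parent.red + (d / u) * (1.0 - parent.red)
            red = min(1.0, max(0.0, red))
        node.red = red
        values[node.node_id] = red
    return REDTable(values)


@dataclass(frozen=True)
class RankAssignment:
    """Rank labels for internal nodes plus per-rank counts."""

    labels: dict[str, str]
    counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["node_id", "rank"]
        )


def _validate_intervals(intervals: Mapping[str, tuple[float, float]]) -> None:
    spans = sorted(intervals.items(), key=lambda kv: kv[1][0])
    for (_, (lo, hi)) in spans:
        if not lo < hi:
            raise ValidationError(f"empty interval ({lo}, {hi})")
    for (r1, (_, hi1)), (r2, (lo2, _)) in zip(spans, spans[1:]):
        if lo2 < hi1:
            raise ValidationError(f"rank intervals {r1!r} and {r2!r} overlap")


def assign_ranks(
    red: REDTable,
    tree: dendropy.Tree,
    intervals: Mapping[str, tuple[float, float]] = DEFAULT_RANK_INTERVALS,
    conflict: str = "midpoint",
) -> RankAssignment:
    """Label internal nodes whose RED falls in a rank's half-open [lo, hi).

    Nested consistency: among candidate nodes of one rank on the same
    root-to-leaf path, only one keeps the label — the node closest to the
    interval midpoint (``conflict="midpoint"``, default) or the one closest
    to the root (``conflict="highest"``).
    """
    _validate_intervals(intervals)
    if conflict not in ("midpoint", "highest"):
        raise ValidationError(f"unknown conflict rule {conflict!r}")
    # ancestor ids per node, for nested-conflict detection
    ancestors: dict[str, frozenset[str]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            ancestors[node.node_id] = frozenset()
        else:
            ancestors[node.node_id] = ancestors[parent.node_id] | {parent.node_id}
    labels: dict[str, str] = {}
    counts: dict[str, int] = {}
    internal = [
        n for n in tree.preorder_node_iter() if not n.is_leaf() and n.parent_node is not None
    ]
    for rank, (lo, hi) in intervals.items():
        candidates = [n for n in internal if lo <= red[n.node_id] < hi]
        mid = (lo + hi) / 2.0
        if conflict == "midpoint":
            candidates.sort(key=lambda n: (abs(red[n.node_id] - mid), n.node_id))
        else:
            candidates.sort(key=lambda n: (red[n.node_id], n.node_id))
        accepted: list[str] = []
        for node in candidates:
            nid = node.node_id
            anc = ancestors[nid]
            if any(a in anc or nid in ancestors[a] for a in accepted):
                continue
            accepted.append(nid)
            labels[nid] = rank
        counts[rank] = len(accepted)
    return RankAssignment(labels, counts)


def intervals_from_reference(
    red: REDTable, reference: Mapping[str, str], half_width: float = 0.1
) -> dict[str, tuple[float, float]]:
    """Rank intervals as median reference RED per rank +/- ``half_width``."""
    by_rank: dict[str, list[float]] = {}
    for node_id, rank in reference.items():
        if node_id not in red.values:
            raise ValidationError(f"reference node {node_id!r} not in RED table")
        by_rank.setdefault(rank, []).append(red[node_id])
    intervals = {
        rank: (float(np.median(v)) - half_width, float(np.median(v)) + half_width)
        for rank, v in by_rank.items()
    }
    _validate_intervals(intervals)
    return intervals
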