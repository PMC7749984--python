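"""Calibrated node dating under a strict clock.

Ages come from a single calibration node and linear scaling: if the
calibration node (e.g. the Pan/Homo MRCA) is fixed at ``cal_age`` YBP, any
node at relative depth ``x`` (substitutions/site) is dated to
``cal_age * x / depth(calibration node)``.

Relative depths are mean root-to-leaf path lengths: the depth of a node is
the average, over its descendant leaves, of the path length from the node to
the leaf.  Because noisy branch-length estimates can put a child's mean
depth above its parent's, depths are monotonicity-repaired in postorder
(``depth(parent) := max(depth(parent), max child depth)``) so ages weakly
decrease from root to leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .errors import TreeError
from .treeutils import leafsets, mrca

__all__ = ["AgeEstimate", "calibrate_ages", "node_depths", "age_of_clade"]


@dataclass(frozen=True)
class AgeEstimate:
    """A dated internal node, identified by its descendant leaf set."""

    clade: frozenset
    depth: float  # substitutions/site
    age: float    # YBP


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Mean leaf-path depth per node, monotonicity-repaired."""
    if not tree.is_rooted:
        raise TreeError("node depths require a rooted tree")
    sums: dict[dendropy.Node, tuple[float, int]] = {}
    depths: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sums[node] = (0.0, 1)
            depths[node] = 0.0
            continue
        total, count = 0.0, 0
        for c in node.child_nodes():
            if c.edge.length is None:
                raise TreeError("node depths require branch lengths on every edge")
            s, k = sums[c]
            total += s + c.edge.length * k
            count += k
        sums[node] = (total, count)
        depth = total / count
        # repair: a parent may not sit below any of its children
        depth = max([depth] + [depths[c] for c in node.child_nodes()])
        depths[node] = depth
    return depths


def calibrate_ages(
    tree: dendropy.Tree,
    cal_node: tuple[str, str],
    cal_age: float,
) -> list[AgeEstimate]:
    """Date every internal node by linear scaling through one calibration.

    ``cal_node`` is given as a pair of leaf labels whose MRCA is the
    calibration node.  The calibration node's age equals ``cal_age`` exactly;
    all other ages scale with relative depth, so they are invariant under
    uniform rescaling of branch lengths.
    """
    depths = node_depths(tree)
    cal = mrca(tree, cal_node)
    d0 = depths[cal]
    if d0 <= 0:
        raise TreeError("calibration node has zero depth; cannot scale ages")
    ls = leafsets(tree)
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        est = AgeEstimate(
            clade=ls[node],
            depth=depths[node],
            age=cal_age * depths[node] / d0,
        )
        out.append(est)
    out.sort(key=lambda e: (-len(e.clade), sorted(e.clade)))
    return out


def age_of_clade(estimates: list[AgeEstimate], labels) -> float:
    """Age of the smallest estimated clade containing all ``labels``
    (i.e. the MRCA of those leaves)."""
    target = frozenset(labels)
    candidates = [e for e in estimates if target <= e.clade]
    if not candidates:
        raise TreeError(f"no clade contains {sorted(target)}")
    return min(candidates, key=lambda e: len(e.clade)).age


def round_age(age: float, granularity: float = 25_000) -> float:
    """Round to the reporting granularity (nearest 25,000 years by default).

    Used only for human-readable report text, never for stored values.
    """
    return round(age / granularity) * granularity
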