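"""Distance-based tree building: neighbor-joining and UPGMA.

Both algorithms are written for determinism across platforms: whenever two
candidate joins have numerically tied criteria, the pair whose (sorted)
cluster keys are lexicographically smallest is chosen.  A cluster's key is
the smallest leaf label it contains.

Neighbor-joining is exact on additive matrices: it returns the unique
generating tree with its branch lengths.  Negative branch-length estimates
(possible on noisy data) are clamped to zero with the deficit transferred to
the sibling branch of the same join, so path lengths through the join are
preserved.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .distances import DistanceMatrix
from .errors import TreeError

__all__ = ["neighbor_joining", "upgma"]

_TIE_REL = 1e-10


def _check(dm: DistanceMatrix, min_taxa: int) -> np.ndarray:
    if len(dm.taxa) < min_taxa:
        raise TreeError(f"need at least {min_taxa} taxa")
    return dm.values.astype(float).copy()


def _tied_argmin(cands: list[tuple[float, tuple[str, str], int, int]]):
    """Minimum criterion with lexicographic tie-breaking on cluster keys."""
    best = min(c[0] for c in cands)
    tol = _TIE_REL * max(1.0, abs(best))
    tied = [c for c in cands if c[0] <= best + tol]
    return min(tied, key=lambda c: c[1])


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining; returns an unrooted dendropy tree."""
    d = _check(dm, 3)
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=name)
        nodes.append(node)
        keys.append(name)
    active = list(range(len(nodes)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        cands = []
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                i, j = active[ai], active[aj]
                cands.append((q, tuple(sorted((keys[i], keys[j]))), i, j))
        _, _, i, j = _tied_argmin(cands)
        dij = d[i, j]
        ri = d[i, active].sum()
        rj = d[j, active].sum()
        li = 0.5 * dij + (ri - rj) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        drow = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new, :-1] = drow
        d[:-1, new] = drow
        d[new, new] = 0.0
        active = [a for a in active if a not in (i, j)] + [new]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].edge.length = max(ln, 0.0)
            root.add_child(nodes[idx])
    else:  # exactly 3 input taxa handled above; this is the 2-cluster tail
        i, j = active
        nodes[i].edge.length = d[i, j] / 2.0
        nodes[j].edge.length = d[i, j] / 2.0
        root.add_child(nodes[i])
        root.add_child(nodes[j])

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage clustering; returns a rooted ultrametric tree.

    Node heights (stored on ``node.height``) are half the average distance
    between the merged clusters; edge lengths are height differences.
    """
    if len(dm.taxa) < 2:
        raise TreeError("need at least 2 taxa")
    d = dm.values.astype(float).copy()
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    sizes: list[int] = []
    heights: list[float] = []
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=name)
        node.height = 0.0
        nodes.append(node)
        keys.append(name)
        sizes.append(1)
        heights.append(0.0)
    active = list(range(len(nodes)))

    while len(active) > 1:
        cands = []
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                cands.append((d[i, j], tuple(sorted((keys[i], keys[j]))), i, j))
        dij, _, i, j = _tied_argmin(cands)
        h = dij / 2.0
        h = max(h, heights[i], heights[j])  # guards tiny numeric inversions
        parent = dendropy.Node()
        parent.height = h
        nodes[i].edge.length = h - heights[i]
        nodes[j].edge.length = h - heights[j]
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new = len(nodes)
        si, sj = sizes[i], sizes[j]
        drow = (si * d[i, :] + sj * d[j, :]) / (si + sj)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new, :-1] = drow
        d[:-1, new] = drow
        d[new, new] = 0.0
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        sizes.append(si + sj)
        heights.append(h)
        active = [a for a in active if a not in (i, j)] + [new]

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return tree
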