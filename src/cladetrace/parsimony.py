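"""Fitch small parsimony and exhaustive topology search at toy scale.

The number of unrooted binary topologies grows as (2n-5)!!, so exhaustive
enumeration is capped at 9 leaves.  Columns are compressed to site patterns
before scoring; ambiguous symbols (``N`` and ``-``) are treated as missing,
i.e. the full state set at that leaf.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .alignment import Alignment
from .errors import TreeError
from .treeutils import leaf_labels

__all__ = [
    "enumerate_topologies",
    "exhaustive_parsimony_search",
    "fitch_score",
    "n_topologies",
]

MAX_ENUM_TAXA = 9

_STATE_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "N": 15, "-": 15,
}


def n_topologies(n: int) -> int:
    """(2n-5)!! — the number of unrooted binary topologies on n >= 3 leaves."""
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 5
    return out


def _site_patterns(aln: Alignment, labels: Sequence[str]):
    """Compress columns (restricted to ``labels``) into (pattern, weight)."""
    seqs = [aln.get(lb) for lb in labels]
    counts = Counter(zip(*seqs))
    patterns = np.array(
        [[_STATE_MASK[ch] for ch in col] for col in counts],
        dtype=np.uint8,
    ).T  # shape (n_labels, n_patterns)
    weights = np.array(list(counts.values()), dtype=np.int64)
    return patterns, weights


def _fitch_on_children(masks: list[np.ndarray], weights: np.ndarray) -> tuple[np.ndarray, int]:
    """Fold child state-sets pairwise left-to-right (exact for the root
    trifurcation of an unrooted binary tree)."""
    acc = masks[0]
    score = 0
    for m in masks[1:]:
        inter = acc & m
        empty = inter == 0
        score += int(weights[empty].sum())
        acc = np.where(empty, acc | m, inter)
    return acc, score


def fitch_score(tree: dendropy.Tree, aln: Alignment) -> int:
    """Minimum number of state changes on ``tree`` summed over sites."""
    labels = sorted(leaf_labels(tree))
    missing = [lb for lb in labels if lb not in aln]
    if missing:
        raise TreeError(f"tree leaves absent from alignment: {missing}")
    idx = {lb: i for i, lb in enumerate(labels)}
    patterns, weights = _site_patterns(aln, labels)
    total = 0
    masks: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = patterns[idx[node.taxon.label]]
        else:
            child_masks = [masks.pop(c) for c in node.child_nodes()]
            acc, score = _fitch_on_children(child_masks, weights)
            masks[node] = acc
            total += score
    return total


# -- enumeration ------------------------------------------------------------


def _edge_list_topologies(n: int) -> Iterator[list[tuple[int, int]]]:
    """Unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal nodes are numbered from n upward; generated by stepwise
    insertion of leaf k into every edge of every (k-1)-leaf topology.
    """

    # leaves are 0..n-1, internal nodes n..2n-3; the first internal node (n)
    # is the centre of the 3-leaf star every topology grows from
    def rec(k: int, edges: list[tuple[int, int]], next_internal: int):
        if k == n:
            yield edges
            return
        for e in range(len(edges)):
            u, v = edges[e]
            w = next_internal
            new_edges = edges[:e] + edges[e + 1:] + [(u, w), (w, v), (w, k)]
            yield from rec(k + 1, new_edges, next_internal + 1)

    star = [(n, 0), (n, 1), (n, 2)]
    if n == 3:
        yield star
    else:
        yield from rec(3, star, n + 1)


def _edges_to_tree(edges, taxa: Sequence[str]) -> dendropy.Tree:
    n = len(taxa)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    nodes = {n: tree.seed_node}  # root at the first internal node

    stack = [n]
    seen = {n}
    while stack:
        u = stack.pop()
        for v in sorted(adj[u]):
            if v in seen:
                continue
            seen.add(v)
            node = dendropy.Node()
            if v < n:
                node.taxon = tns.require_taxon(label=taxa[v])
            nodes[u].add_child(node)
            nodes[v] = node
            stack.append(v)
    return tree


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[dendropy.Tree]:
    """Yield every unrooted binary topology on ``taxa`` exactly once."""
    taxa = list(taxa)
    n = len(taxa)
    if not 3 <= n <= MAX_ENUM_TAXA:
        raise TreeError(
            f"exhaustive enumeration supports 3..{MAX_ENUM_TAXA} taxa, got {n}"
        )
    for edges in _edge_list_topologies(n):
        yield _edges_to_tree(edges, taxa)


def _fast_fitch_edges(edges, n: int, patterns: np.ndarray, weights: np.ndarray) -> int:
    """Fitch score straight off an edge list (avoids tree construction)."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = n
    total = 0
    masks: dict[int, np.ndarray] = {}
    # iterative postorder
    stack = [(root, -1, False)]
    while stack:
        u, parent, expanded = stack.pop()
        kids = [v for v in adj[u] if v != parent]
        if not kids:  # leaf
            masks[u] = patterns[u]
            continue
        if not expanded:
            stack.append((u, parent, True))
            for v in kids:
                stack.append((v, u, False))
            continue
        acc, score = _fitch_on_children([masks.pop(v) for v in kids], weights)
        masks[u] = acc
        total += score
    return total


def exhaustive_parsimony_search(
    aln: Alignment, reference: dendropy.Tree
) -> tuple[int, int, dict[int, int]]:
    """Score every topology on the reference's leaf set.

    Returns ``(best_score, n_strictly_better_than_reference, margin_histogram)``
    where the histogram counts, for each positive margin ``reference_score -
    score``, how many topologies beat the reference by exactly that many steps.
    """
    taxa = sorted(leaf_labels(reference))
    n = len(taxa)
    if not 3 <= n <= MAX_ENUM_TAXA:
        raise TreeError(
            f"exhaustive search supports 3..{MAX_ENUM_TAXA} taxa, got {n}"
        )
    missing = [lb for lb in taxa if lb not in aln]
    if missing:
        raise TreeError(f"reference leaves absent from alignment: {missing}")
    ref_score = fitch_score(reference, aln)
    patterns, weights = _site_patterns(aln, taxa)
    best = None
    n_better = 0
    hist: dict[int, int] = {}
    for edges in _edge_list_topologies(n):
        s = _fast_fitch_edges(edges, n, patterns, weights)
        if best is None or s < best:
            best = s
        if s < ref_score:
            n_better += 1
            margin = ref_score - s
            hist[margin] = hist.get(margin, 0) + 1
    return best, n_better, hist
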