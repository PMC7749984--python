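"""Shared test helpers: random trees, path-length matrices, SPR moves.

These are the independent oracles for the inference code: a distance matrix
computed from a known tree is additive by construction, so exact recovery
can be asserted; a tree modified by one SPR is the ground truth for the
displaced-taxon search.
"""

from __future__ import annotations

import dendropy
import numpy as np

from cladetrace.distances import DistanceMatrix
from cladetrace.treeutils import leaf_labels, tree_from_newick


def random_binary_tree(rng: np.random.Generator, n: int,
                       min_len: float = 0.05, max_len: float = 1.0) -> dendropy.Tree:
    """Random unrooted binary tree with positive branch lengths, built by
    stepwise insertion of leaves into uniformly chosen edges."""
    taxa = [f"t{i}" for i in range(n)]

    def L() -> float:
        return float(rng.uniform(min_len, max_len))

    tree = tree_from_newick(
        f"({taxa[0]}:{L()},{taxa[1]}:{L()},{taxa[2]}:{L()});", rooted=False
    )
    for label in taxa[3:]:
        edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent_node
        mid, leaf = dendropy.Node(), dendropy.Node()
        leaf.taxon = tree.taxon_namespace.require_taxon(label=label)
        split = float(rng.uniform(0.2, 0.8)) * target.edge.length
        parent.remove_child(target)
        parent.add_child(mid)
        mid.edge.length = target.edge.length - split
        target.edge.length = split
        mid.add_child(target)
        mid.add_child(leaf)
        leaf.edge.length = L()
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree — an additive matrix by construction."""
    labels = sorted(leaf_labels(tree))
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.distance(tax[labels[i]], tax[labels[j]])
    return DistanceMatrix(taxa=tuple(labels), values=M)


def prune_and_regraft_leaf(tree: dendropy.Tree, rng: np.random.Generator):
    """One SPR moving a single random leaf to a random distant edge.

    Returns ``(new_tree, moved_leaf_label)``; the move is rejected and
    retried until the topology actually changes.
    """
    from cladetrace.treeutils import bipartitions, copy_tree

    base = bipartitions(tree)
    while True:
        t = copy_tree(tree)
        leaves = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        label = leaves[int(rng.integers(len(leaves)))]
        leaf = next(lf for lf in t.leaf_node_iter() if lf.taxon.label == label)
        parent = leaf.parent_node
        parent.remove_child(leaf)
        # suppress the degree-2 node left behind
        if len(parent.child_nodes()) == 1:
            only = parent.child_nodes()[0]
            gp = parent.parent_node
            parent.remove_child(only)
            if gp is None:
                t.seed_node = only
            else:
                only.edge.length = (only.edge.length or 0) + (parent.edge.length or 0)
                gp.remove_child(parent)
                gp.add_child(only)
        edges = [nd for nd in t.preorder_node_iter() if nd.parent_node is not None]
        target = edges[int(rng.integers(len(edges)))]
        gp = target.parent_node
        mid = dendropy.Node()
        half = (target.edge.length or 1.0) / 2
        gp.remove_child(target)
        gp.add_child(mid)
        mid.edge.length = half
        target.edge.length = half
        mid.add_child(target)
        leaf.edge.length = leaf.edge.length or 0.5
        mid.add_child(leaf)
        if bipartitions(t) != base:
            return t, label
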