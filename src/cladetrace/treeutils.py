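"""Helpers around :class:`dendropy.Tree`.

cladetrace uses dendropy trees as its phylogeny container throughout.  All
comparisons between trees are label-based (each tree owns a private taxon
namespace), which keeps operations such as bipartition comparison and
restriction independent of namespace bookkeeping.

Node ages, when present, live on ``node.age`` in years before present (YBP);
branch lengths are in substitutions/site unless a function says otherwise.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy

from .errors import TreeError

__all__ = [
    "Bipartition",
    "bipartitions",
    "build_dated_tree",
    "copy_tree",
    "leaf_labels",
    "leafsets",
    "mrca",
    "restrict",
    "root_with_outgroup",
    "set_branch_lengths_from_ages",
    "tree_from_newick",
    "to_newick",
    "unroot",
]


class Bipartition:
    """A split of a leaf set into two non-empty blocks.

    Canonical orientation: the block *not* containing the reference taxon
    (by default the lexicographically smallest label in the split) is listed
    first.  Equality and hashing ignore orientation.
    """

    __slots__ = ("blocks", "_key")

    def __init__(self, a: Iterable[str], b: Iterable[str], reference: str | None = None):
        a, b = frozenset(a), frozenset(b)
        if not a or not b:
            raise TreeError("bipartition blocks must both be non-empty")
        if a & b:
            raise TreeError("bipartition blocks must be disjoint")
        if reference is None:
            reference = min(min(a), min(b))
        if reference in a:
            a, b = b, a
        self.blocks = (a, b)
        self._key = frozenset((a, b))

    def __eq__(self, other):
        return isinstance(other, Bipartition) and self._key == other._key

    def __hash__(self):
        return hash(self._key)

    def __repr__(self):
        fmt = lambda s: "{" + ",".join(sorted(s)) + "}"
        return f"Bipartition({fmt(self.blocks[0])} | {fmt(self.blocks[1])})"

    @property
    def leaves(self) -> frozenset:
        return self.blocks[0] | self.blocks[1]

    def is_trivial(self) -> bool:
        return min(len(self.blocks[0]), len(self.blocks[1])) == 1

    def smaller_block(self) -> frozenset:
        a, b = self.blocks
        if len(a) != len(b):
            return min(self.blocks, key=len)
        return min(self.blocks, key=lambda s: sorted(s))


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def leafsets(tree: dendropy.Tree) -> Mapping[dendropy.Node, frozenset]:
    """Map each node to the frozenset of leaf labels below it (postorder)."""
    out: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset((node.taxon.label,))
        else:
            acc: set = set()
            for c in node.child_nodes():
                acc |= out[c]
            out[node] = frozenset(acc)
    return out


def mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the given leaf labels (rooted sense)."""
    target = frozenset(labels)
    if not target:
        raise TreeError("mrca of an empty label set is undefined")
    ls = leafsets(tree)
    if not target <= ls[tree.seed_node]:
        missing = sorted(target - ls[tree.seed_node])
        raise TreeError(f"labels not in tree: {missing}")
    node = tree.seed_node
    while True:
        nxt = None
        for c in node.child_nodes():
            if target <= ls[c]:
                nxt = c
                break
        if nxt is None:
            return node
        node = nxt


def bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> set[Bipartition]:
    """The set of splits induced by the tree's edges (unrooted reading)."""
    all_leaves = leaf_labels(tree)
    ls = leafsets(tree)
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        a = ls[node]
        b = all_leaves - a
        if not a or not b:
            continue
        bp = Bipartition(a, b)
        if include_trivial or not bp.is_trivial():
            out.add(bp)
    return out


def copy_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Structural deep copy (labels, branch lengths, node ages); fresh namespace."""
    tns = dendropy.TaxonNamespace()
    new = dendropy.Tree(taxon_namespace=tns)
    new.is_rooted = tree.is_rooted

    def rec(src: dendropy.Node, dst: dendropy.Node) -> None:
        dst.edge.length = src.edge.length
        if getattr(src, "age", None) is not None:
            dst.age = src.age
        if src.is_leaf():
            dst.taxon = tns.require_taxon(label=src.taxon.label)
            return
        for c in src.child_nodes():
            child = dendropy.Node()
            dst.add_child(child)
            rec(c, child)

    rec(tree.seed_node, new.seed_node)
    return new


def restrict(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Topology of ``tree`` restricted to ``labels`` (unifurcations suppressed).

    Only topology and leaf labels survive; branch lengths and ages do not.
    """
    keep = frozenset(labels)
    present = leaf_labels(tree)
    if not keep <= present:
        raise TreeError(f"labels not in tree: {sorted(keep - present)}")
    if len(keep) < 2:
        raise TreeError("restriction needs at least two leaves")

    def rec(node):
        if node.is_leaf():
            return node.taxon.label if node.taxon.label in keep else None
        kids = [r for r in (rec(c) for c in node.child_nodes()) if r is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return kids

    nested = rec(tree.seed_node)
    tns = dendropy.TaxonNamespace()
    new = dendropy.Tree(taxon_namespace=tns)
    new.is_rooted = tree.is_rooted

    def build(spec, dst):
        if isinstance(spec, str):
            dst.taxon = tns.require_taxon(label=spec)
            return
        for sub in spec:
            child = dendropy.Node()
            dst.add_child(child)
            build(sub, child)

    build(nested, new.seed_node)
    return new


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge, splitting it at its midpoint.

    The input is treated as unrooted; the returned tree is rooted, with the
    outgroup leaf and the ingroup as the root's two children.
    """
    t = copy_tree(tree)
    leaf = None
    for lf in t.leaf_node_iter():
        if lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")
    parent = leaf.parent_node
    if parent is None:
        raise TreeError("cannot root a single-leaf tree")
    if parent is not t.seed_node:
        t.reseed_at(
            parent,
            collapse_unrooted_basal_bifurcation=False,
            suppress_unifurcations=True,
        )
    parent = leaf.parent_node
    pendant = leaf.edge.length
    parent.remove_child(leaf)
    if len(parent.child_nodes()) == 1:
        # degree-2 basal node left behind: merge its edge into the child's
        only = parent.child_nodes()[0]
        parent.remove_child(only)
        if parent.edge.length or only.edge.length:
            only.edge.length = (parent.edge.length or 0.0) + (only.edge.length or 0.0)
        parent = only
    root = dendropy.Node()
    half = None if pendant is None else pendant / 2.0
    leaf.edge.length = half
    parent.edge.length = half
    root.add_child(leaf)
    root.add_child(parent)
    t.seed_node = root
    t.is_rooted = True
    return t


def unroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Return an unrooted copy (root bifurcation collapsed)."""
    t = copy_tree(tree)
    t.deroot()
    t.is_rooted = False
    return t


def build_dated_tree(spec) -> dendropy.Tree:
    """Build a dated rooted tree from a nested spec.

    ``spec`` is either a leaf label (str), or ``(age_ybp, [children...])``.
    Leaves get age 0.  Branch lengths are left unset (derive them from ages
    with :func:`set_branch_lengths_from_ages`).
    """
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def rec(node_spec, dst):
        if isinstance(node_spec, str):
            dst.taxon = tns.require_taxon(label=node_spec)
            dst.age = 0.0
            return
        age, children = node_spec
        dst.age = float(age)
        if len(children) < 2:
            raise TreeError("internal nodes need at least two children")
        for c in children:
            child = dendropy.Node()
            dst.add_child(child)
            rec(c, child)

    rec(spec, tree.seed_node)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is not None and not (parent.age > node.age):
            raise TreeError(
                f"node ages must strictly decrease root->leaf "
                f"(parent {parent.age} vs child {node.age})"
            )
    return tree


def set_branch_lengths_from_ages(tree: dendropy.Tree, rate: float = 1.0) -> dendropy.Tree:
    """Set each edge length to (parent age - child age) * rate, in place."""
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            node.edge.length = None
            continue
        if getattr(node, "age", None) is None or getattr(parent, "age", None) is None:
            raise TreeError("tree is not fully dated")
        node.edge.length = (parent.age - node.age) * rate
    return tree


def tree_from_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             taxon_namespace=dendropy.TaxonNamespace())
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        + "\n"
    )
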