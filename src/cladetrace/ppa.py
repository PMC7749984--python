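"""Progressive phylogenetic analysis (PPA).

PPA grows a phylogenetic sampling one taxon at a time: at every step the
tree is re-inferred from scratch on the enlarged taxon set (full rebuild,
not grafting), the newcomer's attachment edge relative to the previous
step's tree is recorded, and each labelled taxon group is re-classified as
monophyletic, paraphyletic or polyphyletic on the outgroup-rooted tree.

Classification: a group is monophyletic iff it equals the leaf set of its
MRCA; it is paraphyletic iff the remainder of that MRCA clade (the clade's
leaves minus the group) is itself monophyletic — i.e. the group is a clade
minus one nested clade; otherwise it is polyphyletic.  The outgroup is
excluded before classifying.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

from .alignment import Alignment
from .distances import distance_matrix
from .errors import TreeError
from .parsimony import MAX_ENUM_TAXA, enumerate_topologies, fitch_score
from .treebuild import neighbor_joining
from .treeutils import (
    Bipartition,
    bipartitions,
    leaf_labels,
    leafsets,
    mrca,
    restrict,
    root_with_outgroup,
)

__all__ = [
    "MonophylyVerdict",
    "PlacementRecord",
    "attachment_edge",
    "monophyly_status",
    "ppa_run",
]


@dataclass(frozen=True)
class MonophylyVerdict:
    status: str  # "monophyletic" | "paraphyletic" | "polyphyletic"
    witness: frozenset  # leaves of the group's MRCA clade


def monophyly_status(
    tree: dendropy.Tree,
    group: Iterable[str],
    outgroup: str | None = None,
) -> MonophylyVerdict:
    """Classify ``group`` on a rooted tree.

    The outgroup (if given) is removed before classification and may belong
    to neither the group nor its complement.
    """
    if not tree.is_rooted:
        raise TreeError("monophyly classification requires a rooted tree")
    group = frozenset(group)
    ingroup = leaf_labels(tree)
    if outgroup is not None:
        if outgroup in group:
            raise TreeError("the outgroup may not be part of a classified group")
        ingroup = ingroup - {outgroup}
        tree = restrict(tree, ingroup)
    if not group:
        raise TreeError("cannot classify an empty group")
    if not group < ingroup:
        raise TreeError(
            "group must be a proper subset of the ingroup leaves"
        )
    ls = leafsets(tree)
    clade = ls[mrca(tree, group)]
    if clade == group:
        return MonophylyVerdict("monophyletic", clade)
    remainder = clade - group
    if ls[mrca(tree, remainder)] == remainder:
        return MonophylyVerdict("paraphyletic", clade)
    return MonophylyVerdict("polyphyletic", clade)


@dataclass(frozen=True)
class PlacementRecord:
    """One PPA step: which taxon was added, where it attached, and the
    group-status snapshot on the rebuilt, outgroup-rooted tree."""

    step: int
    taxon: str
    attachment: Bipartition
    topology_shifted: bool
    tree: dendropy.Tree  # rooted snapshot
    group_status: Mapping[str, MonophylyVerdict]


def attachment_edge(
    prev: dendropy.Tree,
    curr: dendropy.Tree,
    taxon: str,
) -> tuple[Bipartition, bool]:
    """The edge of ``prev`` on which ``taxon`` attached in ``curr``.

    Removing the taxon's pendant edge from ``curr`` merges two edges into
    one; if the restriction of ``curr`` agrees with ``prev`` that merged
    edge corresponds to exactly one edge of ``prev`` (returned with flag
    ``False``).  Otherwise the nearest ``prev`` edge by bipartition overlap
    is returned with the ``topology shifted`` flag ``True``.
    """
    prev_leaves = leaf_labels(prev)
    curr_leaves = leaf_labels(curr)
    if taxon in prev_leaves or curr_leaves != prev_leaves | {taxon}:
        raise TreeError(
            f"leaf sets must satisfy leaves(curr) == leaves(prev) + {{{taxon!r}}}"
        )
    ls = leafsets(curr)
    target = None
    for node in curr.preorder_node_iter():
        if node.is_leaf() and node.taxon.label == taxon:
            target = node
            break
    parent = target.parent_node
    # the merged edge splits prev's leaves into (side containing parent's
    # other subtrees) vs (the rest)
    below = (ls[parent] - {taxon}) if parent is not None else frozenset()
    if not below or below == prev_leaves:
        # attached at the seed: pick the unrooted split through any sibling
        sibs = [c for c in parent.child_nodes() if c is not target]
        below = ls[sibs[0]] - {taxon}
    bp = Bipartition(below, prev_leaves - below)
    prev_edges = bipartitions(prev, include_trivial=True)
    shifted = bipartitions(restrict(curr, prev_leaves)) != bipartitions(prev)
    if not shifted and bp in prev_edges:
        return bp, False
    # topology shifted: nearest prev edge by block overlap
    a = bp.blocks[0]
    def score(edge: Bipartition) -> tuple[int, list]:
        ea, eb = edge.blocks
        mismatch = min(len(a ^ ea), len(a ^ eb))
        return (mismatch, sorted(edge.smaller_block()))
    nearest = min(prev_edges, key=score)
    return nearest, True


def _infer(aln: Alignment, names: Sequence[str], method: str,
           distance_model: str) -> dendropy.Tree:
    sub = aln.subset(names)
    if method == "nj":
        return neighbor_joining(distance_matrix(sub, model=distance_model))
    if method == "parsimony":
        if len(names) > MAX_ENUM_TAXA:
            raise TreeError(
                f"parsimony inference enumerates all topologies and is capped "
                f"at {MAX_ENUM_TAXA} taxa (got {len(names)}); use method='nj'"
            )
        best_tree, best_score = None, None
        for tree in enumerate_topologies(sorted(names)):
            s = fitch_score(tree, sub)
            if best_score is None or s < best_score:
                best_tree, best_score = tree, s
        return best_tree
    raise TreeError(f"unknown inference method {method!r}")


def ppa_run(
    aln: Alignment,
    core: Iterable[str],
    additions: Sequence[str],
    *,
    method: str = "nj",
    distance_model: str = "K2P",
    outgroup: str,
    groups: Mapping[str, Sequence[str]],
) -> tuple[list[PlacementRecord], dendropy.Tree]:
    """Run PPA: infer the core tree, then add taxa one at a time.

    ``groups`` maps group labels to leaf names; at each step only the group
    members present in the current sampling are classified (singletons and
    absent groups report as monophyletic/are skipped).  Returns the ordered
    placement records and the final rooted tree.
    """
    core = list(dict.fromkeys(core))
    if outgroup not in core:
        raise TreeError("the outgroup must be part of the PPA core")
    missing = [n for n in list(core) + list(additions) if n not in aln]
    if missing:
        raise TreeError(f"taxa absent from alignment: {missing}")

    def classify(rooted: dendropy.Tree) -> dict[str, MonophylyVerdict]:
        present = leaf_labels(rooted) - {outgroup}
        out = {}
        for label, members in groups.items():
            members_here = frozenset(members) & present
            if not members_here or members_here == present:
                continue
            out[label] = monophyly_status(rooted, members_here, outgroup=outgroup)
        return out

    sampling = list(core)
    prev_unrooted = _infer(aln, sampling, method, distance_model)
    records: list[PlacementRecord] = []
    for step, taxon in enumerate(additions, start=1):
        sampling.append(taxon)
        curr_unrooted = _infer(aln, sampling, method, distance_model)
        edge, shifted = attachment_edge(prev_unrooted, curr_unrooted, taxon)
        rooted = root_with_outgroup(curr_unrooted, outgroup)
        records.append(
            PlacementRecord(
                step=step,
                taxon=taxon,
                attachment=edge,
                topology_shifted=shifted,
                tree=rooted,
                group_status=classify(rooted),
            )
        )
        prev_unrooted = curr_unrooted
    final = root_with_outgroup(prev_unrooted, outgroup)
    return records, final
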