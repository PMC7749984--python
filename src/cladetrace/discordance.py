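"""Gene-tree/species-tree discordance and introgression direction.

The comparison is purely topological, in the spirit of the sister-group
argument for mtDNA capture: if a reference (species/nuDNA) topology and a
test (mtDNA) topology disagree, the smallest leaf set whose removal
reconciles them names the displaced taxa, and for each displaced taxon the
donor lineage is read off the test tree as the smallest reference clade
containing the taxon's new sister group.

Concretely, for a capture of the form "recipient X now sits inside/beside
clade D": the forward scenario (donor D -> recipient X) predicts X sister to
D while X's original sister group keeps its other relationships; the reverse
scenario (donor X -> recipients in D) would instead pull the D taxa over to
X's side of the reference topology.  The rule trace records the taxon's
sister group in both trees and which configuration matched.

No branch-length or likelihood test is performed; a topological argument
cannot by itself exclude other sources of discordance (e.g. lineage
sorting), and reports say so.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy

from .errors import TreeError
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
    "DirectionCall",
    "DiscordanceReport",
    "DisplacementSearch",
    "build_report",
    "compare_topologies",
    "displaced_taxa",
    "infer_introgression_direction",
]


def _same_topology(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    return bipartitions(a) == bipartitions(b)


def compare_topologies(
    ref: dendropy.Tree, test: dendropy.Tree
) -> tuple[set[Bipartition], set[Bipartition]]:
    """(shared, conflicting) non-trivial bipartitions; the size of the
    conflicting set is the Robinson-Foulds distance."""
    if leaf_labels(ref) != leaf_labels(test):
        raise TreeError("trees must share an identical leaf set")
    br, bt = bipartitions(ref), bipartitions(test)
    return br & bt, br ^ bt


@dataclass(frozen=True)
class DisplacementSearch:
    """Result of the minimal-prune search.

    ``taxa`` is the smallest reconciling leaf set (lexicographic
    tie-breaking), or ``None`` if no subset of size <= ``max_k`` reconciles
    the trees.
    """

    taxa: frozenset | None
    max_k: int

    @property
    def reconciled(self) -> bool:
        return self.taxa is not None


def displaced_taxa(
    ref: dendropy.Tree, test: dendropy.Tree, max_k: int = 3
) -> DisplacementSearch:
    """Smallest leaf set whose removal makes the restricted topologies equal.

    Exhaustive over subsets of size 0..max_k, smallest first; ties at equal
    size broken lexicographically.  An empty result set means the trees
    already agree.
    """
    leaves = leaf_labels(ref)
    if leaves != leaf_labels(test):
        raise TreeError("trees must share an identical leaf set")
    # keep at least 3 leaves after pruning; the exact search is capped at 3
    max_k = max(0, min(max_k, 3, len(leaves) - 3))
    if _same_topology(ref, test):
        return DisplacementSearch(frozenset(), max_k)
    ordered = sorted(leaves)
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(ordered, k):
            keep = leaves - set(combo)
            if _same_topology(restrict(ref, keep), restrict(test, keep)):
                result = DisplacementSearch(frozenset(combo), max_k)
                _assert_reconciles(ref, test, result.taxa)
                return result
    return DisplacementSearch(None, max_k)


def _assert_reconciles(ref, test, taxa):
    keep = leaf_labels(ref) - taxa
    if not _same_topology(restrict(ref, keep), restrict(test, keep)):
        raise TreeError("internal error: reported prune set does not reconcile")


@dataclass(frozen=True)
class DirectionCall:
    donor: frozenset      # leaves of the donor clade in the reference tree
    recipient: str        # the displaced taxon
    trace: dict

    def describe(self) -> str:
        donor = "{" + ",".join(sorted(self.donor)) + "}"
        return (
            f"donor lineage {donor} -> recipient {self.recipient} "
            f"({self.trace['configuration']} configuration)"
        )


def infer_introgression_direction(
    ref: dendropy.Tree,
    test: dendropy.Tree,
    taxon: str,
    outgroup: str | None = None,
) -> DirectionCall:
    """Direction of the introgression that displaced ``taxon``.

    Both trees may be rooted or unrooted; if an outgroup is given the trees
    are (re)rooted with it so sister groups are read on rooted topologies.
    The donor is the smallest clade of ``ref`` that contains the displaced
    taxon's sister group in ``test``.
    """
    if leaf_labels(ref) != leaf_labels(test):
        raise TreeError("trees must share an identical leaf set")
    search = displaced_taxa(ref, test, max_k=min(3, len(leaf_labels(ref)) - 3))
    if not search.reconciled or taxon not in search.taxa:
        raise TreeError(
            f"{taxon!r} is not a displaced taxon; nothing to infer"
        )
    if outgroup is not None:
        ref = root_with_outgroup(ref, outgroup)
        test = root_with_outgroup(test, outgroup)
        drop = {outgroup}
    elif not (ref.is_rooted and test.is_rooted):
        raise TreeError("direction inference needs rooted trees or an outgroup")
    else:
        drop = set()

    def sister(tree: dendropy.Tree, lb: str) -> frozenset:
        ls = leafsets(tree)
        node = next(
            n for n in tree.leaf_node_iter() if n.taxon.label == lb
        )
        parent = node.parent_node
        sibs = frozenset().union(
            *(ls[c] for c in parent.child_nodes() if c is not node)
        )
        return sibs - drop

    new_sister = sister(test, taxon)
    old_sister = sister(ref, taxon)
    ref_ingroup = restrict(ref, leaf_labels(ref) - drop) if drop else ref
    ls = leafsets(ref_ingroup)
    donor = ls[mrca(ref_ingroup, new_sister)]
    trace = {
        "displaced": taxon,
        "sister_in_reference": old_sister,
        "sister_in_test": new_sister,
        "donor_clade": donor,
        "configuration": "forward",
        "note": (
            "forward: the displaced taxon joins the donor clade while its "
            "reference sister group keeps its other relationships; a reverse "
            "transfer would instead carry the donor-side taxa to the "
            "displaced taxon's reference position"
        ),
    }
    return DirectionCall(donor=donor, recipient=taxon, trace=trace)


@dataclass(frozen=True)
class DiscordanceReport:
    shared: frozenset
    conflicting: frozenset
    displacement: DisplacementSearch
    directions: tuple[DirectionCall, ...]

    @property
    def rf_distance(self) -> int:
        return len(self.conflicting)

    @property
    def concordant(self) -> bool:
        return self.rf_distance == 0

    def describe(self) -> str:
        lines = [
            f"shared bipartitions:      {len(self.shared)}",
            f"conflicting bipartitions: {len(self.conflicting)} (RF distance)",
        ]
        if self.concordant:
            lines.append("trees are concordant; no introgression inferred")
        elif self.displacement.reconciled:
            taxa = ",".join(sorted(self.displacement.taxa))
            lines.append(f"displaced taxa: {{{taxa}}}")
            for call in self.directions:
                lines.append("direction: " + call.describe())
            lines.append(
                "note: direction is inferred from topology alone; branch "
                "lengths and alternative discordance processes are not tested"
            )
        else:
            lines.append(
                f"irreconcilable within k={self.displacement.max_k} leaf removals"
            )
        return "\n".join(lines)


def build_report(
    ref: dendropy.Tree,
    test: dendropy.Tree,
    outgroup: str | None = None,
    max_k: int = 3,
) -> DiscordanceReport:
    """Full discordance analysis of a reference vs a test topology."""
    shared, conflicting = compare_topologies(ref, test)
    search = displaced_taxa(ref, test, max_k=max_k)
    directions = []
    if search.reconciled and search.taxa:
        for taxon in sorted(search.taxa):
            directions.append(
                infer_introgression_direction(ref, test, taxon, outgroup=outgroup)
            )
    return DiscordanceReport(
        shared=frozenset(shared),
        conflicting=frozenset(conflicting),
        displacement=search,
        directions=tuple(directions),
    )
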