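"""Topology comparison, displaced taxa, introgression direction."""

import pytest

import cladetrace as ct
from cladetrace.errors import TreeError
from cladetrace.treeutils import bipartitions, leaf_labels, restrict

from util import prune_and_regraft_leaf, random_binary_tree

REF = "((Pan,(Hsnd,(SH_Hsnn,Hsnn_star))),(Mbuti,Lund));"   # species shape
TEST = "((Pan,(Hsnd,SH_Hsnn)),(Hsnn_star,(Mbuti,Lund)));"  # mtDNA shape


class TestCompare:
    def test_identical_trees_share_everything(self, rng):
        tree = random_binary_tree(rng, 7)
        shared, conflicting = ct.compare_topologies(tree, tree)
        assert conflicting == set()
        assert shared == bipartitions(tree)

    def test_fig_shaped_trees_conflict(self):
        shared, conflicting = ct.compare_topologies(
            ct.tree_from_newick(REF), ct.tree_from_newick(TEST)
        )
        assert len(conflicting) > 0

    def test_single_nni_gives_rf_two(self):
        # one NNI swap (B <-> E) across the AB|CDE edge replaces exactly
        # one bipartition
        a = ct.tree_from_newick("((A,B),(C,D),E);")
        b = ct.tree_from_newick("((A,E),(C,D),B);")
        _, conflicting = ct.compare_topologies(a, b)
        assert len(conflicting) == 2

    def test_leaf_set_mismatch_rejected(self, rng):
        with pytest.raises(TreeError):
            ct.compare_topologies(
                random_binary_tree(rng, 5), random_binary_tree(rng, 6)
            )


class TestDisplacedTaxa:
    def test_identical_trees_need_no_pruning(self, rng):
        tree = random_binary_tree(rng, 6)
        assert ct.displaced_taxa(tree, tree).taxa == frozenset()

    def test_fig_shaped_trees_displace_the_recipient(self):
        search = ct.displaced_taxa(
            ct.tree_from_newick(REF), ct.tree_from_newick(TEST)
        )
        assert search.taxa == frozenset({"Hsnn_star"})

    def test_spr_moved_leaf_reconciles_and_search_finds_a_minimal_set(self, rng):
        """After a single-leaf SPR the displaced search finds a one-leaf
        reconciling set (not necessarily the moved leaf: when the move stays
        local another single removal can heal the conflict too, and ties are
        broken lexicographically), and pruning it reconciles the trees."""
        for _ in range(20):
            ref = random_binary_tree(rng, int(rng.integers(6, 9)))
            test, moved = prune_and_regraft_leaf(ref, rng)
            search = ct.displaced_taxa(ref, test, max_k=3)
            assert search.reconciled
            assert len(search.taxa) == 1  # the moved leaf is a witness set
            keep_moved = leaf_labels(ref) - {moved}
            assert bipartitions(restrict(ref, keep_moved)) == bipartitions(
                restrict(test, keep_moved)
            )
            keep = leaf_labels(ref) - search.taxa
            assert bipartitions(restrict(ref, keep)) == bipartitions(
                restrict(test, keep)
            )

    def test_single_leaf_answers_agree_with_direct_scan(self, rng):
        ref = random_binary_tree(rng, 7)
        test, moved = prune_and_regraft_leaf(ref, rng)
        search = ct.displaced_taxa(ref, test, max_k=1)
        if search.reconciled:
            scan = [
                lb
                for lb in sorted(leaf_labels(ref))
                if bipartitions(restrict(ref, leaf_labels(ref) - {lb}))
                == bipartitions(restrict(test, leaf_labels(ref) - {lb}))
            ]
            assert search.taxa == frozenset({min(scan)})

    def test_irreconcilable_within_k_is_reported_not_raised(self, rng):
        ref = random_binary_tree(rng, 9)
        test = ref
        for _ in range(4):  # four independent leaf moves
            test, _ = prune_and_regraft_leaf(test, rng)
        search = ct.displaced_taxa(ref, test, max_k=1)
        # either one removal heals it (moves overlapped) or we get the
        # explicit irreconcilable result
        assert search.reconciled or search.taxa is None


class TestDirection:
    def test_forward_capture_names_the_donor_clade(self):
        call = ct.infer_introgression_direction(
            ct.tree_from_newick(REF), ct.tree_from_newick(TEST),
            "Hsnn_star", outgroup="Pan",
        )
        assert call.recipient == "Hsnn_star"
        assert call.donor == frozenset({"Mbuti", "Lund"})
        assert call.trace["sister_in_reference"] == frozenset({"SH_Hsnn"})

    def test_reverse_capture_is_the_mirror_call(self):
        # Hss displaced into the Neanderthal clade: (Hss,Hsnn_star) sister
        # to SH_Hsnn — the opposite-direction configuration
        ref = ct.tree_from_newick(
            "((Pan,(Hsnd,(SH_Hsnn,Hsnn_star))),(Hss,Other));"
        )
        test = ct.tree_from_newick(
            "((Pan,(Hsnd,(SH_Hsnn,(Hsnn_star,Hss)))),Other);"
        )
        call = ct.infer_introgression_direction(ref, test, "Hss", outgroup="Pan")
        assert call.recipient == "Hss"
        assert call.donor == frozenset({"Hsnn_star"})

    def test_concordant_trees_have_nothing_to_infer(self, rng):
        tree = random_binary_tree(rng, 6)
        with pytest.raises(TreeError):
            ct.infer_introgression_direction(tree, tree, "t0")

    def test_non_displaced_taxon_rejected(self):
        with pytest.raises(TreeError):
            ct.infer_introgression_direction(
                ct.tree_from_newick(REF), ct.tree_from_newick(TEST),
                "Mbuti", outgroup="Pan",
            )


class TestReport:
    def test_report_on_simulated_scenario(self, mtdna_alignment, preset):
        tree = ct.neighbor_joining(ct.distance_matrix(mtdna_alignment))
        ref = restrict(preset.species_tree, leaf_labels(tree))
        report = ct.build_report(ref, tree, outgroup="Pan")
        assert not report.concordant
        assert report.displacement.taxa == frozenset({"Hsnn_star"})
        (call,) = report.directions
        assert call.recipient == "Hsnn_star"
        assert call.donor == frozenset(
            {"Mbuti", "San", "Yoruba1", "Yoruba2", "Lund", "French"}
        )
        text = report.describe()
        assert "Hsnn_star" in text and "donor" in text

    def test_concordant_report(self, rng):
        tree = random_binary_tree(rng, 6)
        report = ct.build_report(tree, tree)
        assert report.concordant
        assert report.directions == ()
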