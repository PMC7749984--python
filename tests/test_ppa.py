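"""Monophyly classification, attachment edges and progressive analysis."""

import pytest

import cladetrace as ct
from cladetrace.errors import TreeError
from cladetrace.ppa import attachment_edge
from cladetrace.treeutils import Bipartition, bipartitions

from util import prune_and_regraft_leaf, random_binary_tree


@pytest.fixture
def rooted6():
    # (((m,s),(y,l)),(n1,n2)) with outgroup o
    return ct.tree_from_newick("((((m,s),(y,l)),(n1,n2)),o);", rooted=True)


class TestMonophyly:
    def test_singleton_is_monophyletic(self, rooted6):
        v = ct.monophyly_status(rooted6, {"m"}, outgroup="o")
        assert v.status == "monophyletic"
        assert v.witness == frozenset({"m"})

    def test_clade_is_monophyletic(self, rooted6):
        assert ct.monophyly_status(rooted6, {"m", "s"}, outgroup="o").status == \
            "monophyletic"

    def test_clade_minus_nested_clade_is_paraphyletic(self):
        # Africans (M, S, Y1, Y2) span a clade whose only other member is
        # the nested non-African Lund lineage
        tree = ct.tree_from_newick(
            "(((((M,S),(Y1,(Y2,L)))),(n1,n2)),o);", rooted=True
        )
        v = ct.monophyly_status(tree, {"M", "S", "Y1", "Y2"}, outgroup="o")
        assert v.status == "paraphyletic"
        assert v.witness == frozenset({"M", "S", "Y1", "Y2", "L"})

    def test_scattered_group_is_polyphyletic(self):
        tree = ct.tree_from_newick("(((a1,b1),(a2,b2)),o);", rooted=True)
        assert ct.monophyly_status(tree, {"a1", "a2"}, outgroup="o").status == \
            "polyphyletic"

    def test_empty_or_full_group_rejected(self, rooted6):
        with pytest.raises(TreeError):
            ct.monophyly_status(rooted6, set(), outgroup="o")
        with pytest.raises(TreeError):
            ct.monophyly_status(
                rooted6, {"m", "s", "y", "l", "n1", "n2"}, outgroup="o"
            )

    def test_invariant_under_irrelevant_taxa(self, rooted6):
        """Adding taxa outside the group's MRCA clade does not change the
        verdict."""
        smaller = ct.tree_from_newick("(((m,s),(y,l)),o);", rooted=True)
        v1 = ct.monophyly_status(smaller, {"m", "s"}, outgroup="o")
        v2 = ct.monophyly_status(rooted6, {"m", "s"}, outgroup="o")
        assert v1.status == v2.status == "monophyletic"

    def test_invariant_under_leaf_order(self):
        a = ct.tree_from_newick("(((m,s),(y,l)),o);", rooted=True)
        b = ct.tree_from_newick("(((l,y),(s,m)),o);", rooted=True)
        for group in ({"m", "s"}, {"m", "y"}, {"s", "l"}):
            assert (
                ct.monophyly_status(a, group, outgroup="o").status
                == ct.monophyly_status(b, group, outgroup="o").status
            )


class TestAttachmentEdge:
    def test_graft_onto_known_edge_is_found(self, rng):
        prev = random_binary_tree(rng, 6)
        curr, moved = None, None
        # graft a new leaf x onto the pendant edge of t1
        import dendropy
        from cladetrace.treeutils import copy_tree

        curr = copy_tree(prev)
        leaf_t1 = next(
            lf for lf in curr.leaf_node_iter() if lf.taxon.label == "t1"
        )
        parent = leaf_t1.parent_node
        mid, x = dendropy.Node(), dendropy.Node()
        x.taxon = curr.taxon_namespace.require_taxon(label="x")
        parent.remove_child(leaf_t1)
        parent.add_child(mid)
        mid.add_child(leaf_t1)
        mid.add_child(x)
        edge, shifted = attachment_edge(prev, curr, "x")
        assert not shifted
        assert edge.smaller_block() == frozenset({"t1"})

    def test_extra_rearrangement_sets_the_flag(self, rng):
        prev = random_binary_tree(rng, 7)
        moved_tree, moved = prune_and_regraft_leaf(prev, rng)
        # graft a fresh leaf onto the rearranged tree: restriction of curr
        # to prev's leaves no longer matches prev
        import dendropy

        leaf0 = next(
            lf for lf in moved_tree.leaf_node_iter() if lf.taxon.label == "t0"
        )
        parent = leaf0.parent_node
        mid, x = dendropy.Node(), dendropy.Node()
        x.taxon = moved_tree.taxon_namespace.require_taxon(label="x")
        parent.remove_child(leaf0)
        parent.add_child(mid)
        mid.add_child(leaf0)
        mid.add_child(x)
        edge, shifted = attachment_edge(prev, moved_tree, "x")
        assert shifted
        assert isinstance(edge, Bipartition)

    def test_leaf_set_mismatch_rejected(self, rng):
        prev = random_binary_tree(rng, 5)
        curr = random_binary_tree(rng, 5)
        with pytest.raises(TreeError):
            attachment_edge(prev, curr, "t0")


class TestPpaRun:
    def test_identical_sequence_attaches_at_twin_pendant_edge(self):
        seqs = {
            "o": "ACGTACGTACGTACGTTTTT",
            "a": "ACGTACGTACGAACGTACGA",
            "b": "ACGTACGAACGTACGTACGT",
            "c": "ACGAACGTACGTACGTACGC",
        }
        seqs["twin"] = seqs["a"]
        aln = ct.Alignment(list(seqs.items()))
        records, _ = ct.ppa_run(
            aln, ["o", "a", "b", "c"], ["twin"],
            method="nj", distance_model="p", outgroup="o",
            groups={"g": ["a", "twin"]},
        )
        assert records[0].attachment.smaller_block() == frozenset({"a"})
        assert not records[0].topology_shifted

    def test_full_rebuild_matches_one_shot_inference(self, mtdna_alignment, preset):
        core = ["Pan", "Hsnd", "SH_Hsnn", "Hsnn_star", "Mbuti", "Lund"]
        adds = ["San", "Yoruba1", "Yoruba2"]
        records, final = ct.ppa_run(
            mtdna_alignment, core, adds, outgroup="Pan", groups=preset.groups
        )
        one_shot = ct.neighbor_joining(
            ct.distance_matrix(mtdna_alignment.subset(core + adds))
        )
        assert bipartitions(final) == bipartitions(one_shot)
        assert [r.step for r in records] == [1, 2, 3]

    def test_replays_the_scenario_progression(self, mtdna_alignment, preset):
        """San joins Mbuti; the Yorubas land on the Lund side; the final
        African verdict is paraphyletic."""
        core = ["Pan", "Hsnd", "SH_Hsnn", "Hsnn_star", "Mbuti", "Lund"]
        records, final = ct.ppa_run(
            mtdna_alignment, core, ["San", "Yoruba1", "Yoruba2"],
            outgroup="Pan", groups=preset.groups,
        )
        assert records[0].taxon == "San"
        assert records[0].attachment.smaller_block() == frozenset({"Mbuti"})
        assert records[-1].group_status["african"].status == "paraphyletic"

    def test_parsimony_backend_capped(self, mtdna_alignment, preset):
        names = list(mtdna_alignment.names)
        with pytest.raises(TreeError, match="nj"):
            ct.ppa_run(
                mtdna_alignment, names, [], method="parsimony",
                outgroup="Pan", groups=preset.groups,
            )

    def test_outgroup_must_be_in_core(self, mtdna_alignment, preset):
        with pytest.raises(TreeError):
            ct.ppa_run(
                mtdna_alignment, ["Mbuti", "San", "Lund"], [],
                outgroup="Pan", groups=preset.groups,
            )
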