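"""Scenario presets, locus-tree derivation and sequence simulation."""

import math

import pytest

import cladetrace as ct
from cladetrace.errors import ScenarioError
from cladetrace.scenarios import IntrogressionEvent, ScenarioSpec
from cladetrace.treeutils import bipartitions, leafsets, mrca


class TestPreset:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ScenarioError):
            ct.build_scenario_preset("atlantis")

    def test_preset_encodes_the_scenario_dates(self, preset):
        tree = preset.species_tree
        assert tree.seed_node.age == 8_000_000  # Pan/Homo calibration point
        hs = mrca(tree, ["Hsnd", "Mbuti"])
        assert hs.age == 800_000
        assert mrca(tree, ["Mbuti", "Lund"]).age == 250_000
        assert mrca(tree, ["Yoruba1", "Lund"]).age == 225_000
        assert mrca(tree, ["Yoruba2", "Lund"]).age == 180_000
        assert mrca(tree, ["Lund", "French"]).age == 125_000
        (event,) = preset.introgression_events
        assert event.age == 500_000
        assert event.locus == "mtDNA"
        assert event.recipient == ("Hsnn_star",)

    def test_ages_strictly_decrease_towards_leaves(self, preset):
        for node in preset.species_tree.preorder_node_iter():
            for child in node.child_nodes():
                assert child.age < node.age

    def test_preset_is_deterministic(self):
        a = ct.build_scenario_preset("fig1_fig3")
        b = ct.build_scenario_preset("fig1_fig3")
        assert a.taxa == b.taxa
        assert bipartitions(a.species_tree) == bipartitions(b.species_tree)

    def test_groups_partition_the_taxa(self, preset):
        union = [n for g in preset.groups.values() for n in g]
        assert sorted(union) == sorted(preset.names)
        assert preset.outgroup == "Pan"


class TestLocusTree:
    def test_locus_without_events_equals_species_tree(self, preset):
        nu = ct.derive_locus_tree(preset, "nuDNA")
        assert bipartitions(nu) == bipartitions(preset.species_tree)
        ages = {frozenset(v): k.age for k, v in leafsets(nu).items()}
        ages_sp = {frozenset(v): k.age
                   for k, v in leafsets(preset.species_tree).items()}
        assert ages == ages_sp

    def test_mtdna_capture_moves_the_recipient(self, preset, mtdna_tree):
        # Hsnn_star becomes sister to the Hss clade at the event age ...
        joint = mrca(mtdna_tree, ["Hsnn_star", "Mbuti"])
        ls = leafsets(mtdna_tree)
        assert ls[joint] == frozenset(
            ["Hsnn_star", "Mbuti", "San", "Yoruba1", "Yoruba2", "Lund", "French"]
        )
        assert joint.age == 500_000
        # ... and SH_Hsnn pairs with Hsnd on the other side
        assert ls[mrca(mtdna_tree, ["SH_Hsnn", "Hsnd"])] == frozenset(
            ["SH_Hsnn", "Hsnd"]
        )

    def test_locus_and_species_tree_differ_by_one_leaf(self, preset, mtdna_tree):
        report = ct.displaced_taxa(preset.species_tree, mtdna_tree, max_k=3)
        assert report.taxa == frozenset({"Hsnn_star"})

    def test_event_older_than_divergence_rejected(self, preset):
        with pytest.raises(ScenarioError):
            ScenarioSpec(
                taxa=preset.taxa,
                species_tree=preset.species_tree,
                introgression_events=(
                    IntrogressionEvent(
                        donor=("Mbuti",), recipient=("Hsnn_star",),
                        age=900_000, locus="mtDNA",
                    ),
                ),
            )

    def test_event_after_recipient_divergence_rejected(self, preset):
        # the lineage {SH_Hsnn, Hsnn_star} splits at 600k, so it no longer
        # exists as a single branch at 550k
        with pytest.raises(ScenarioError):
            ScenarioSpec(
                taxa=preset.taxa,
                species_tree=preset.species_tree,
                introgression_events=(
                    IntrogressionEvent(
                        donor=("Mbuti",),
                        recipient=("SH_Hsnn", "Hsnn_star"),
                        age=550_000, locus="mtDNA",
                    ),
                ),
            )


class TestSimulation:
    def test_zero_rate_gives_identical_sequences(self, preset, mtdna_tree):
        from dataclasses import replace

        spec0 = replace(preset, clock_rate=0.0)
        aln = ct.simulate_alignment(mtdna_tree, spec0, seed=5)
        seqs = {seq for _, seq in aln}
        assert len(seqs) == 1

    def test_same_seed_is_byte_identical(self, preset, mtdna_tree):
        a = ct.simulate_alignment(mtdna_tree, preset, seed=11).to_fasta()
        b = ct.simulate_alignment(mtdna_tree, preset, seed=11).to_fasta()
        assert a == b

    def test_different_seeds_differ(self, preset, mtdna_tree):
        a = ct.simulate_alignment(mtdna_tree, preset, seed=11).to_fasta()
        b = ct.simulate_alignment(mtdna_tree, preset, seed=12).to_fasta()
        assert a != b

    def test_undated_tree_rejected(self, preset):
        undated = ct.tree_from_newick("((A:1,B:1):1,C:2);", rooted=True)
        with pytest.raises(ScenarioError):
            ct.simulate_alignment(undated, preset)

    def test_jc69_pairwise_distance_matches_closed_form(self):
        """Observed p-distance on a two-leaf clock tree converges to
        (3/4)(1 - exp(-(8/3) r T)) — checked at 10^5 sites, 3 MC SE."""
        from cladetrace.treeutils import build_dated_tree

        T, r, L = 1_000_000, 1.5e-8, 100_000
        tree = build_dated_tree((T, ["A", "B"]))
        spec = ScenarioSpec(
            taxa=(("A", "african"), ("B", "non_african")),
            species_tree=tree,
            clock_rate=r, seq_length=L, model="JC69", seed=0,
        )
        aln = ct.simulate_alignment(tree, spec, seed=42)
        p_obs = ct.p_distance(aln.get("A"), aln.get("B"))
        p_exp = 0.75 * (1.0 - math.exp(-(8.0 / 3.0) * r * T))
        se = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se

    def test_k2p_transition_transversion_split_matches_closed_form(self):
        from cladetrace.simulate import transition_probabilities
        from cladetrace.treeutils import build_dated_tree

        T, r, L, kappa = 2_000_000, 1.5e-8, 100_000, 4.0
        tree = build_dated_tree((T, ["A", "B"]))
        spec = ScenarioSpec(
            taxa=(("A", "african"), ("B", "non_african")),
            species_tree=tree,
            clock_rate=r, seq_length=L, model="K2P", kappa=kappa, seed=0,
        )
        aln = ct.simulate_alignment(tree, spec, seed=7)
        from cladetrace.distances import _ts_tv_proportions

        P_obs, Q_obs = _ts_tv_proportions(aln.get("A"), aln.get("B"))
        _, p_ts, p_tv = transition_probabilities(2 * r * T, kappa)
        for obs, exp in ((P_obs, p_ts), (Q_obs, 2 * p_tv)):
            se = math.sqrt(exp * (1 - exp) / L)
            assert abs(obs - exp) < 3 * se
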