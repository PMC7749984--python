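"""One-command reproduction of the scenario analysis.

``run_paper_scenario`` simulates the configured scenario's mtDNA locus,
runs the full inference chain (distances -> NJ -> outgroup rooting ->
calibrated dating -> PPA -> discordance) and returns a :class:`RunReport`
that can serialise itself to a directory of plain-text artifacts.  Reports
are a pure function of (config, seed): two runs with the same inputs write
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .chronology import round_age
from .distances import write_phylip_matrix
from .errors import ScenarioError
from .model import MtdnaPhylogenyModel, MtdnaPhylogenyResults
from .scenarios import (
    IntrogressionEvent,
    ScenarioSpec,
    build_scenario_preset,
    derive_locus_tree,
)
from .treeutils import (
    build_dated_tree,
    leafsets,
    set_branch_lengths_from_ages,
    to_newick,
    tree_from_newick,
)

__all__ = ["RunReport", "run_paper_scenario", "read_config", "write_config"]

#: Default PPA schedule for the fig1_fig3 preset: the core holds one
#: representative per deep lineage plus the basal modern pair (Mbuti, Lund);
#: San and the Yorubas are then added stepwise.
PRESET_PPA = {
    "fig1_fig3": (
        ("Pan", "Hsnd", "SH_Hsnn", "Hsnn_star", "Mbuti", "Lund"),
        ("San", "Yoruba1", "Yoruba2"),
    ),
}


# -- flat key-value scenario config ----------------------------------------


def write_config(spec: ScenarioSpec, path=None) -> str:
    """Serialise a scenario as a flat key=value file.

    The species tree is stored as Newick with branch lengths in years
    (ages are recoverable because tips are extant); events as
    ``donor>recipient@age:locus`` with ``+``-joined lineage labels.
    """
    tree = set_branch_lengths_from_ages(_copy_for_config(spec))
    events = ";".join(
        "+".join(ev.donor) + ">" + "+".join(ev.recipient)
        + f"@{ev.age:g}:{ev.locus}"
        for ev in spec.introgression_events
    )
    lines = [
        "taxa=" + ",".join(f"{n}={g}" for n, g in spec.taxa),
        "species_tree=" + to_newick(tree).strip(),
        "events=" + events,
        f"clock_rate={spec.clock_rate:g}",
        f"seq_length={spec.seq_length}",
        f"model={spec.model}",
        f"kappa={spec.kappa:g}",
        f"seed={spec.seed}",
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _copy_for_config(spec: ScenarioSpec):
    from .treeutils import copy_tree

    return copy_tree(spec.species_tree)


def read_config(source) -> ScenarioSpec:
    """Parse a config written by :func:`write_config`."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    kv = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    try:
        taxa = tuple(
            tuple(item.split("=", 1)) for item in kv["taxa"].split(",") if item
        )
        tree = tree_from_newick(kv["species_tree"], rooted=True)
        _ages_from_year_lengths(tree)
        events = []
        if kv.get("events"):
            for item in kv["events"].split(";"):
                rest, _, locus = item.rpartition(":")
                lineages, _, age = rest.rpartition("@")
                donor, _, recipient = lineages.partition(">")
                events.append(
                    IntrogressionEvent(
                        donor=tuple(donor.split("+")),
                        recipient=tuple(recipient.split("+")),
                        age=float(age),
                        locus=locus,
                    )
                )
        return ScenarioSpec(
            taxa=taxa,
            species_tree=tree,
            introgression_events=tuple(events),
            clock_rate=float(kv["clock_rate"]),
            seq_length=int(kv["seq_length"]),
            model=kv["model"],
            kappa=float(kv["kappa"]),
            seed=int(kv["seed"]),
        )
    except (KeyError, ValueError) as exc:
        raise ScenarioError(f"invalid scenario config: {exc}") from None


def _ages_from_year_lengths(tree) -> None:
    """Recover node ages from branch lengths in years (extant tips)."""
    # age = max distance to a descendant leaf along year-scaled branches
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
        else:
            node.age = max(
                c.age + (c.edge.length or 0.0) for c in node.child_nodes()
            )


# -- the end-to-end run ------------------------------------------------------


@dataclass
class RunReport:
    """All artifacts of one scenario run, serialisable as plain text."""

    config_text: str
    seed: int
    locus: str
    alignment_fasta: str
    species_tree_newick: str
    locus_tree_newick: str
    inferred_tree_newick: str
    distance_matrix_text: str
    results: MtdnaPhylogenyResults

    def summary_text(self) -> str:
        res = self.results
        lines = [res.summary(), "Headline date chain (rounded to 25,000 yr):"]
        for label, leaves in _HEADLINE_NODES:
            try:
                age = res.age_of(leaves)
            except Exception:
                continue
            lines.append(f"  {label:46s} ~{round_age(age):>9,.0f} YBP")
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.txt").write_text(self.config_text)
        (out / "alignment.fasta").write_text(self.alignment_fasta)
        (out / "species_tree.nwk").write_text(self.species_tree_newick)
        (out / f"{self.locus}_true_tree.nwk").write_text(self.locus_tree_newick)
        (out / "inferred_tree.nwk").write_text(self.inferred_tree_newick)
        (out / "distances.phy").write_text(self.distance_matrix_text)
        (out / "ages.tsv").write_text(
            self.results.age_table.to_csv(sep="\t", index=False)
        )
        (out / "placements.tsv").write_text(self._placements_tsv())
        (out / "summary.txt").write_text(self.summary_text())

    def _placements_tsv(self) -> str:
        rows = ["step\ttaxon\tattachment_edge\ttopology_shifted\tgroup_status"]
        for rec in self.results.placements:
            side = "+".join(sorted(rec.attachment.smaller_block()))
            status = ";".join(
                f"{k}={v.status}" for k, v in sorted(rec.group_status.items())
            )
            rows.append(
                f"{rec.step}\t{rec.taxon}\t{side}\t{rec.topology_shifted}\t{status}"
            )
        return "\n".join(rows) + "\n"


_HEADLINE_NODES = [
    ("basal Hs mtDNA divergence", ("Hsnd", "Mbuti")),
    ("Hsnn_star joins the Hss lineage", ("Hsnn_star", "Mbuti")),
    ("basal divergence among extant humans", ("Mbuti", "Lund")),
    ("first Yoruba / non-African divergence", ("Yoruba1", "Lund")),
    ("basal non-African divergence", ("Lund", "French")),
]


def run_paper_scenario(config="fig1_fig3", seed: int = 0,
                       locus: str = "mtDNA") -> RunReport:
    """Simulate and analyse one scenario replicate.

    ``config`` is a preset name or a :class:`ScenarioSpec`; ``seed`` overrides
    the spec's seed for the sequence simulation.
    """
    if isinstance(config, ScenarioSpec):
        spec = config.with_seed(seed)
        preset = None
    else:
        spec = build_scenario_preset(config).with_seed(seed)
        preset = config
    core_adds = PRESET_PPA.get(preset)
    model = MtdnaPhylogenyModel.from_scenario(
        spec,
        locus=locus,
        ppa_core=core_adds[0] if core_adds else None,
        ppa_additions=core_adds[1] if core_adds else (),
    )
    results = model.fit()

    from .treeutils import copy_tree

    species = set_branch_lengths_from_ages(copy_tree(spec.species_tree))
    locus_tree = set_branch_lengths_from_ages(derive_locus_tree(spec, locus))
    return RunReport(
        config_text=write_config(spec),
        seed=seed,
        locus=locus,
        alignment_fasta=model.alignment.to_fasta(),
        species_tree_newick=to_newick(species),
        locus_tree_newick=to_newick(locus_tree),
        inferred_tree_newick=to_newick(results.tree),
        distance_matrix_text=write_phylip_matrix(results.distance_matrix_)
        if results.distance_matrix_ is not None
        else "",
        results=results,
    )
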