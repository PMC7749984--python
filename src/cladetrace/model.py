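"""Model/Results interface over the whole analysis chain.

:class:`MtdnaPhylogenyModel` bundles an alignment with the analysis
configuration (taxon groups, outgroup, calibration, inference method);
``fit()`` runs distances -> tree inference -> outgroup rooting -> calibrated
dating -> PPA -> discordance and returns a :class:`MtdnaPhylogenyResults`
carrying the estimates and a ``summary()`` table, in the style of
statsmodels' model objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .alignment import Alignment
from .chronology import AgeEstimate, age_of_clade, calibrate_ages, round_age
from .discordance import DiscordanceReport, build_report
from .distances import DistanceMatrix, distance_matrix
from .errors import TreeError
from .ppa import MonophylyVerdict, PlacementRecord, monophyly_status, ppa_run, _infer
from .treeutils import leaf_labels, restrict, root_with_outgroup

__all__ = ["MtdnaPhylogenyModel", "MtdnaPhylogenyResults"]


class MtdnaPhylogenyModel:
    """End-to-end phylogenetic analysis of one locus alignment.

    Parameters
    ----------
    alignment:
        The sequences to analyse.
    groups:
        Mapping of group label (e.g. ``african``) to member taxon names.
    outgroup:
        Leaf used to root every inferred tree.
    calibration:
        ``((leaf_a, leaf_b), age_ybp)``: the MRCA of the pair is fixed at
        the given age and all other node ages scale linearly with depth.
    method, distance_model:
        Tree inference backend (``"nj"`` or ``"parsimony"``) and the
        distance correction used for NJ.
    reference_tree:
        Optional species-tree topology; when given, the fitted locus tree
        is compared against it and introgression direction is inferred.
    ppa_core, ppa_additions:
        Optional progressive-analysis schedule.  When both are given the
        fit also replays the stepwise taxon addition and records placements.
    """

    def __init__(
        self,
        alignment: Alignment,
        *,
        groups: Mapping[str, Sequence[str]],
        outgroup: str,
        calibration: tuple[tuple[str, str], float],
        method: str = "nj",
        distance_model: str = "K2P",
        reference_tree: dendropy.Tree | None = None,
        ppa_core: Sequence[str] | None = None,
        ppa_additions: Sequence[str] = (),
    ):
        if outgroup not in alignment:
            raise TreeError(f"outgroup {outgroup!r} not in alignment")
        self.alignment = alignment
        self.groups = {k: tuple(v) for k, v in groups.items()}
        self.outgroup = outgroup
        self.calibration = ((calibration[0][0], calibration[0][1]), float(calibration[1]))
        self.method = method
        self.distance_model = distance_model
        self.reference_tree = reference_tree
        self.ppa_core = list(ppa_core) if ppa_core is not None else None
        self.ppa_additions = list(ppa_additions)

    @classmethod
    def from_scenario(cls, spec, locus: str = "mtDNA", seed: int | None = None,
                      **overrides) -> "MtdnaPhylogenyModel":
        """Simulate the scenario's locus alignment and set the model up to
        analyse it against the scenario's species tree."""
        from .scenarios import derive_locus_tree, simulate_alignment

        locus_tree = derive_locus_tree(spec, locus)
        aln = simulate_alignment(locus_tree, spec, seed=seed)
        ingroup = [n for n in spec.names if n != spec.outgroup]
        defaults = dict(
            groups=spec.groups,
            outgroup=spec.outgroup,
            calibration=((spec.outgroup, ingroup[0]), spec.species_tree.seed_node.age),
            distance_model="K2P" if spec.model == "K2P" else "JC69",
            reference_tree=spec.species_tree,
        )
        defaults.update(overrides)
        return cls(aln, **defaults)

    def fit(self) -> "MtdnaPhylogenyResults":
        dm = distance_matrix(self.alignment, model=self.distance_model) \
            if self.method == "nj" else None
        unrooted = _infer(
            self.alignment, self.alignment.names, self.method, self.distance_model
        )
        rooted = root_with_outgroup(unrooted, self.outgroup)
        ages = calibrate_ages(rooted, *self.calibration)

        verdicts: dict[str, MonophylyVerdict] = {}
        ingroup = leaf_labels(rooted) - {self.outgroup}
        for label, members in self.groups.items():
            members_here = frozenset(members) & ingroup
            if not members_here or members_here == ingroup:
                continue
            verdicts[label] = monophyly_status(rooted, members_here,
                                               outgroup=self.outgroup)

        placements: list[PlacementRecord] = []
        ppa_final = None
        if self.ppa_core is not None:
            placements, ppa_final = ppa_run(
                self.alignment,
                self.ppa_core,
                self.ppa_additions,
                method=self.method,
                distance_model=self.distance_model,
                outgroup=self.outgroup,
                groups=self.groups,
            )

        discordance = None
        if self.reference_tree is not None:
            ref = restrict(self.reference_tree, leaf_labels(unrooted))
            discordance = build_report(ref, unrooted, outgroup=self.outgroup)

        return MtdnaPhylogenyResults(
            model=self,
            distance_matrix_=dm,
            tree=unrooted,
            rooted_tree=rooted,
            age_estimates=ages,
            group_verdicts=verdicts,
            placements=placements,
            ppa_final_tree=ppa_final,
            discordance=discordance,
        )


@dataclass
class MtdnaPhylogenyResults:
    """Estimates from one :meth:`MtdnaPhylogenyModel.fit` call."""

    model: MtdnaPhylogenyModel
    distance_matrix_: DistanceMatrix | None
    tree: dendropy.Tree
    rooted_tree: dendropy.Tree
    age_estimates: list[AgeEstimate]
    group_verdicts: Mapping[str, MonophylyVerdict]
    placements: list[PlacementRecord] = field(default_factory=list)
    ppa_final_tree: dendropy.Tree | None = None
    discordance: DiscordanceReport | None = None

    def age_of(self, labels) -> float:
        """Calibrated age (YBP) of the MRCA of the given leaves."""
        return age_of_clade(self.age_estimates, labels)

    @property
    def age_table(self) -> pd.DataFrame:
        rows = [
            {
                "clade": ",".join(sorted(e.clade)),
                "n_leaves": len(e.clade),
                "depth_subs_per_site": e.depth,
                "age_ybp": e.age,
                "age_rounded_ybp": round_age(e.age),
            }
            for e in self.age_estimates
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        (cal_a, cal_b), cal_age = m.calibration
        lines = [
            "MtdnaPhylogenyModel results",
            "===========================",
            f"taxa: {len(m.alignment)}  sites: {m.alignment.length}",
            f"inference: {m.method}"
            + (f" (distance model {m.distance_model})" if m.method == "nj" else ""),
            f"outgroup: {m.outgroup}",
            f"calibration: MRCA({cal_a},{cal_b}) = {cal_age:,.0f} YBP",
            "",
            "Group classification (paraphyly = clade minus one nested clade):",
        ]
        for label in sorted(self.group_verdicts):
            v = self.group_verdicts[label]
            lines.append(f"  {label:12s} {v.status}")
        lines += ["", "Calibrated node ages (rounded to 25,000 yr in this table):"]
        for e in self.age_estimates:
            if len(e.clade) == len(m.alignment.names):
                name = "root"
            else:
                name = ",".join(sorted(e.clade))
            if len(name) > 56:
                name = name[:53] + "..."
            lines.append(f"  {round_age(e.age):>12,.0f} YBP  MRCA[{name}]")
        if self.placements:
            lines += ["", "PPA placements:"]
            for rec in self.placements:
                flag = " (topology shifted)" if rec.topology_shifted else ""
                side = ",".join(sorted(rec.attachment.smaller_block()))
                lines.append(f"  step {rec.step}: +{rec.taxon} on edge [{side}]{flag}")
        if self.discordance is not None:
            lines += ["", "Discordance vs reference topology:"]
            lines += ["  " + ln for ln in self.discordance.describe().splitlines()]
        return "\n".join(lines) + "\n"

    def __repr__(self):
        return (
            f"<MtdnaPhylogenyResults: {len(self.model.alignment)} taxa, "
            f"{len(self.age_estimates)} dated nodes>"
        )
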