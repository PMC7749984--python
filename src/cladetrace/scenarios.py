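"""Dated species/locus-tree scenarios with mtDNA-capture introgression.

A :class:`ScenarioSpec` holds the generative truth for the whole pipeline:
a dated species tree (node ages in YBP, tips extant), a set of introgression
events, and the clock/substitution-model parameters used to evolve sequences
along the resulting locus trees.

The bundled ``fig1_fig3`` preset encodes a hominin history in which the
chimpanzee outgroup (Pan) splits from Homo at 8 MYBP; the Homo sapiens stem
splits into the modern (Hss) and Neanderthal/Denisovan (Hsn) lineages at
800,000 YBP; the Hsn branch divides into Denisovans (Hsnd) and Neanderthals,
the latter splitting into the Sima de los Huesos lineage (SH_Hsnn) and the
main Neanderthal lineage (Hsnn_star); and the Hss crown diversifies at
250,000 YBP (Mbuti/San vs the rest), 225,000 and 180,000 YBP (two Yoruba
lineages leaving the non-African stem) and 125,000 YBP (basal split among
non-Africans, Lund vs French).  A single mitochondrial capture carries the
Hss-stem mtDNA into Hsnn_star at 500,000 YBP, so the mtDNA tree joins
Hsnn_star to the Hss clade while the species (nuDNA) tree keeps it beside
SH_Hsnn — the discordance the downstream modules are built to detect.

An introgression event names donor and recipient *lineages* by a set of
leaf labels: the lineage is the branch ancestral to the MRCA of those leaves
at the event's age.  Only full lineage capture (whole-locus replacement) is
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import dendropy

from .alignment import Alignment
from .errors import ScenarioError, TreeError
from .simulate import simulate_alignment as _simulate_alignment
from .treeutils import build_dated_tree, copy_tree, mrca

__all__ = [
    "GROUP_LABELS",
    "IntrogressionEvent",
    "ScenarioSpec",
    "build_scenario_preset",
    "derive_locus_tree",
    "simulate_alignment",
]

GROUP_LABELS = ("african", "non_african", "archaic", "outgroup")

#: Default strict-clock rate, substitutions/site/year.  Together with the
#: 8 MYBP calibration depth this gives a Pan-human distance of ~0.24
#: substitutions/site: strong signal, far from saturation.
DEFAULT_CLOCK_RATE = 1.5e-8

#: mtDNA-like locus length in sites.
DEFAULT_SEQ_LENGTH = 16_500

#: mtDNA-typical transition/transversion rate ratio for the K2P model.
DEFAULT_KAPPA = 4.0


@dataclass(frozen=True)
class IntrogressionEvent:
    """Whole-locus capture: the recipient lineage's locus copy is replaced
    by the donor lineage's copy at ``age`` YBP."""

    donor: tuple[str, ...]
    recipient: tuple[str, ...]
    age: float
    locus: str

    def __post_init__(self):
        object.__setattr__(self, "donor", tuple(self.donor))
        object.__setattr__(self, "recipient", tuple(self.recipient))
        if self.age <= 0:
            raise ScenarioError("event age must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """Dated species tree + events + clock/model parameters."""

    taxa: tuple[tuple[str, str], ...]
    species_tree: dendropy.Tree
    introgression_events: tuple[IntrogressionEvent, ...] = ()
    clock_rate: float = DEFAULT_CLOCK_RATE
    seq_length: int = DEFAULT_SEQ_LENGTH
    model: str = "K2P"
    kappa: float = DEFAULT_KAPPA
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple((n, g) for n, g in self.taxa))
        object.__setattr__(
            self, "introgression_events", tuple(self.introgression_events)
        )
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.clock_rate < 0:
            raise ScenarioError("clock_rate must be >= 0")
        if self.seq_length <= 0:
            raise ScenarioError("seq_length must be positive")
        if self.model not in ("JC69", "K2P"):
            raise ScenarioError(f"unknown substitution model {self.model!r}")
        if self.kappa <= 0:
            raise ScenarioError("kappa must be positive")
        names = [n for n, _ in self.taxa]
        if len(set(names)) != len(names):
            raise ScenarioError("duplicate taxon names")
        for name, group in self.taxa:
            if group not in GROUP_LABELS:
                raise ScenarioError(
                    f"taxon {name!r} has unknown group {group!r}; "
                    f"expected one of {GROUP_LABELS}"
                )
        tree_leaves = {lf.taxon.label for lf in self.species_tree.leaf_node_iter()}
        if tree_leaves != set(names):
            raise ScenarioError("species tree leaves do not match the taxon table")
        for node in self.species_tree.preorder_node_iter():
            parent = node.parent_node
            if getattr(node, "age", None) is None:
                raise ScenarioError("species tree must be fully dated")
            if parent is not None and not (parent.age > node.age):
                raise ScenarioError("node ages must strictly decrease root->leaf")
        for ev in self.introgression_events:
            _lineage_edge(self.species_tree, ev.donor, ev.age)
            _lineage_edge(self.species_tree, ev.recipient, ev.age)
            div = mrca(self.species_tree, set(ev.donor) | set(ev.recipient)).age
            if not ev.age < div:
                raise ScenarioError(
                    f"event at {ev.age} YBP is not younger than the "
                    f"donor/recipient divergence at {div} YBP"
                )

    # -- conveniences ------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.taxa)

    def group(self, label: str) -> tuple[str, ...]:
        if label not in GROUP_LABELS:
            raise ScenarioError(f"unknown group label {label!r}")
        return tuple(n for n, g in self.taxa if g == label)

    @property
    def groups(self) -> dict[str, tuple[str, ...]]:
        return {g: self.group(g) for g in GROUP_LABELS if self.group(g)}

    @property
    def outgroup(self) -> str:
        og = self.group("outgroup")
        if len(og) != 1:
            raise ScenarioError("scenario must have exactly one outgroup taxon")
        return og[0]

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


def _lineage_edge(tree: dendropy.Tree, labels: Iterable[str], age: float):
    """The (child, parent) edge on the root-path of MRCA(labels) spanning ``age``.

    The lineage named by ``labels`` must exist as a single branch at that
    time: ``child.age <= age < parent.age``.
    """
    node = mrca(tree, labels)
    if node.age > age:
        raise ScenarioError(
            f"lineage {sorted(labels)} has already diverged at {age} YBP "
            f"(its MRCA is at {node.age} YBP)"
        )
    while node.parent_node is not None and node.parent_node.age <= age:
        node = node.parent_node
    if node.parent_node is None:
        raise ScenarioError(
            f"age {age} YBP is at or above the root of the tree"
        )
    return node, node.parent_node


# -- presets ----------------------------------------------------------------

_FIG1_FIG3_TAXA = (
    ("Pan", "outgroup"),
    ("Hsnd", "archaic"),
    ("SH_Hsnn", "archaic"),
    ("Hsnn_star", "archaic"),
    ("Mbuti", "african"),
    ("San", "african"),
    ("Yoruba1", "african"),
    ("Yoruba2", "african"),
    ("Lund", "non_african"),
    ("French", "non_african"),
)

_HSS_LEAVES = ("Mbuti", "San", "Yoruba1", "Yoruba2", "Lund", "French")


def _fig1_fig3_species_tree() -> dendropy.Tree:
    # Ages in YBP.  The Hsn-internal splits (700k, 600k) and the Mbuti/San
    # split (150k) are not externally constrained; they only need to bracket
    # the 500k introgression and the 250k crown age.
    spec = (
        8_000_000,
        [
            "Pan",
            (
                800_000,
                [
                    (
                        250_000,
                        [
                            (150_000, ["Mbuti", "San"]),
                            (
                                225_000,
                                [
                                    "Yoruba1",
                                    (180_000, ["Yoruba2", (125_000, ["Lund", "French"])]),
                                ],
                            ),
                        ],
                    ),
                    (700_000, ["Hsnd", (600_000, ["SH_Hsnn", "Hsnn_star"])]),
                ],
            ),
        ],
    )
    return build_dated_tree(spec)


def build_scenario_preset(name: str) -> ScenarioSpec:
    """Named scenario presets; ``"fig1_fig3"`` is the hominin mtDNA-capture
    scenario described in the module docstring."""
    if name != "fig1_fig3":
        raise ScenarioError(f"unknown scenario preset {name!r}")
    return ScenarioSpec(
        taxa=_FIG1_FIG3_TAXA,
        species_tree=_fig1_fig3_species_tree(),
        introgression_events=(
            IntrogressionEvent(
                donor=_HSS_LEAVES,
                recipient=("Hsnn_star",),
                age=500_000,
                locus="mtDNA",
            ),
        ),
    )


# -- locus trees -------------------------------------------------------------


def derive_locus_tree(spec: ScenarioSpec, locus: str) -> dendropy.Tree:
    """Species tree with every event on ``locus`` applied.

    Each event detaches the recipient lineage at the event age and
    re-attaches it to the donor lineage at that age; the result is dated and
    ultrametric in time.  Events are applied youngest first.
    """
    tree = copy_tree(spec.species_tree)
    events = sorted(
        (ev for ev in spec.introgression_events if ev.locus == locus),
        key=lambda ev: ev.age,
    )
    for ev in events:
        _apply_event(tree, ev)
    return tree


def _apply_event(tree: dendropy.Tree, ev: IntrogressionEvent) -> None:
    rec_child, rec_parent = _lineage_edge(tree, ev.recipient, ev.age)
    div = mrca(tree, set(ev.donor) | set(ev.recipient)).age
    if not ev.age < div:
        raise ScenarioError(
            f"event at {ev.age} YBP is not younger than the donor/recipient "
            f"divergence at {div} YBP"
        )
    # detach the recipient subtree
    rec_parent.remove_child(rec_child)
    remaining = rec_parent.child_nodes()
    if len(remaining) == 1:
        only = remaining[0]
        gp = rec_parent.parent_node
        rec_parent.remove_child(only)
        if gp is None:
            tree.seed_node = only
        else:
            gp.remove_child(rec_parent)
            gp.add_child(only)
    # re-attach to the donor lineage at the event age
    don_child, don_parent = _lineage_edge(tree, ev.donor, ev.age)
    joint = dendropy.Node()
    joint.age = float(ev.age)
    don_parent.remove_child(don_child)
    don_parent.add_child(joint)
    joint.add_child(don_child)
    joint.add_child(rec_child)


def simulate_alignment(tree: dendropy.Tree, spec: ScenarioSpec,
                       seed: int | None = None) -> Alignment:
    """Evolve sequences along a dated tree under the scenario's clock/model.

    Deterministic for a given seed (``spec.seed`` unless overridden).
    """
    try:
        return _simulate_alignment(
            tree,
            clock_rate=spec.clock_rate,
            seq_length=spec.seq_length,
            model=spec.model,
            kappa=spec.kappa,
            seed=spec.seed if seed is None else seed,
        )
    except TreeError as exc:
        raise ScenarioError(str(exc)) from None
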