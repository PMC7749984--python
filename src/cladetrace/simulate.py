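"""Strict-clock sequence evolution along a dated tree.

Sites evolve independently under JC69 or K2P (Kimura 1980 with
transition/transversion rate ratio ``kappa``); there is no rate
heterogeneity and no indel process, so simulated sequences contain only
``A/C/G/T``.  Expected substitutions on a branch equal branch duration
(years) times the clock rate (substitutions/site/year).

Determinism: one numpy Generator seeded once drives the whole simulation,
consumed in a branch-ordered preorder traversal in which children are
visited in order of their smallest descendant leaf label.  Identical seeds
therefore give byte-identical alignments on any platform.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .alignment import Alignment
from .errors import TreeError

__all__ = ["simulate_alignment", "transition_probabilities"]

# base encoding: transitions are A<->G and C<->T, i.e. code XOR 1
_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)
_DECODE = {0: "A", 1: "G", 2: "C", 3: "T"}


def transition_probabilities(d: float, kappa: float = 1.0) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after ``d`` expected
    substitutions/site under K80 with rate ratio ``kappa`` (kappa=1 is JC69).

    The rate matrix is normalised so that ``d`` is the expected number of
    substitutions: with transversion rate beta = 1/(kappa+2) and transition
    rate alpha = kappa*beta, the total rate alpha + 2*beta equals 1.
    """
    if d < 0:
        raise TreeError("branch length must be non-negative")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return p_same, p_ts, p_tv


def _ordered_children(node: dendropy.Node, min_leaf: dict) -> list[dendropy.Node]:
    return sorted(node.child_nodes(), key=lambda c: min_leaf[c])


def simulate_alignment(
    tree: dendropy.Tree,
    *,
    clock_rate: float,
    seq_length: int,
    model: str = "K2P",
    kappa: float = 4.0,
    seed: int = 0,
) -> Alignment:
    """Simulate an alignment on a dated tree; leaves are emitted in sorted
    label order."""
    if model == "JC69":
        kappa = 1.0
    elif model != "K2P":
        raise TreeError(f"unknown substitution model {model!r}")
    for node in tree.preorder_node_iter():
        if getattr(node, "age", None) is None:
            raise TreeError("simulation requires a fully dated tree")

    min_leaf: dict[dendropy.Node, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            min_leaf[node] = node.taxon.label
        else:
            min_leaf[node] = min(min_leaf[c] for c in node.child_nodes())

    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length, dtype=np.uint8)
    leaf_seqs: dict[str, np.ndarray] = {}

    stack = [(tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = seq
            continue
        # reversed so the lexicographically first child is simulated first
        for child in reversed(_ordered_children(node, min_leaf)):
            d = (node.age - child.age) * clock_rate
            stack.append((child, _evolve_branch(seq, d, kappa, rng)))

    lut = _BASES  # codes 0..3 -> ASCII
    records = []
    for label in sorted(leaf_seqs):
        records.append((label, lut[leaf_seqs[label]].tobytes().decode("ascii")))
    return Alignment(records)


def _evolve_branch(parent: np.ndarray, d: float, kappa: float,
                   rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return parent.copy()
    p_same, p_ts, p_tv = transition_probabilities(d, kappa)
    u = rng.random(parent.shape[0])
    child = parent.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    child[ts] ^= 1   # A<->G, C<->T
    child[tv1] ^= 2  # A<->C, G<->T
    child[tv2] ^= 3  # A<->T, G<->C
    return child
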