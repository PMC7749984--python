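"""Pairwise evolutionary distances.

Observed proportions use pairwise deletion: a site is comparable for a pair
only if both sequences carry an unambiguous base (``A/C/G/T``) there.
Corrections: JC69 (one rate) and K2P (Kimura two-parameter, separate
transition/transversion proportions).  Saturation — an observed proportion
outside a correction's domain — is a hard error, never truncated: on
simulated data it signals a mis-specified scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .errors import SaturationError, TreeError, ZeroComparableSitesError

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "jc69_distance",
    "k2p_distance",
    "p_distance",
    "read_phylip_matrix",
    "write_phylip_matrix",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) with a taxon order."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise TreeError(f"matrix shape {v.shape} does not match {n} taxa")
        if not np.allclose(v, v.T):
            raise TreeError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise TreeError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise TreeError("distances must be finite and non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


def _comparable(a: str, b: str):
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            yield x, y


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching sites among pairwise-comparable sites."""
    if len(a) != len(b):
        raise ZeroComparableSitesError("sequences must have equal length")
    n = diff = 0
    for x, y in _comparable(a, b):
        n += 1
        if x != y:
            diff += 1
    if n == 0:
        raise ZeroComparableSitesError("no comparable sites between sequences")
    return diff / n


def _ts_tv_proportions(a: str, b: str) -> tuple[float, float]:
    """Transition and transversion proportions (pairwise deletion)."""
    n = ts = tv = 0
    for x, y in _comparable(a, b):
        n += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ZeroComparableSitesError("no comparable sites between sequences")
    return ts / n, tv / n


def jc69_distance(p: float) -> float:
    """Jukes-Cantor correction: d = -(3/4) ln(1 - 4p/3), defined for p < 3/4."""
    if not 0 <= p < 0.75:
        raise SaturationError(f"p-distance {p} outside JC69 domain [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 1980 correction from transition (P) and transversion (Q) proportions."""
    if P < 0 or Q < 0:
        raise SaturationError("proportions must be non-negative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"observed proportions P={P}, Q={Q} outside the K2P domain"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _encode(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(codes, valid, purine) uint8/bool arrays of shape (n_taxa, n_sites)."""
    mat = np.frombuffer(
        "".join(seq for _, seq in aln).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.length)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    purine = np.isin(mat, np.frombuffer(b"AG", dtype=np.uint8))
    return mat, valid, purine


def distance_matrix(aln: Alignment, model: str = "K2P") -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` in ``{"p", "JC69", "K2P"}``."""
    model = model.upper() if model.lower() != "p" else "p"
    if model not in ("p", "JC69", "K2P"):
        raise TreeError(f"unknown distance model {model!r}")
    names = aln.names
    if len(names) < 3:
        raise TreeError("distance matrix needs at least 3 taxa")
    n = len(names)
    codes, valid, purine = _encode(aln)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = int(ok.sum())
            pair = f"({names[i]}, {names[j]})"
            if m == 0:
                raise ZeroComparableSitesError(f"pair {pair}: no comparable sites")
            mismatch = ok & (codes[i] != codes[j])
            try:
                if model == "p":
                    d = mismatch.sum() / m
                elif model == "JC69":
                    d = jc69_distance(mismatch.sum() / m)
                else:
                    ts = int((mismatch & (purine[i] == purine[j])).sum())
                    tv = int(mismatch.sum()) - ts
                    d = k2p_distance(ts / m, tv / m)
            except SaturationError as exc:
                raise SaturationError(f"pair {pair}: {exc}") from None
            out[i, j] = out[j, i] = d
    return DistanceMatrix(taxa=tuple(names), values=out)


# -- PHYLIP square matrix I/O ----------------------------------------------


def write_phylip_matrix(dm: DistanceMatrix, path=None) -> str:
    """Relaxed PHYLIP square format (names padded to >= 10 columns)."""
    width = max(10, max(len(t) for t in dm.taxa) + 1)
    lines = [f"{len(dm.taxa):5d}"]
    for i, name in enumerate(dm.taxa):
        row = " ".join(f"{dm.values[i, j]:.8f}" for j in range(len(dm.taxa)))
        lines.append(f"{name:<{width}}{row}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_phylip_matrix(source) -> DistanceMatrix:
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    taxa, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(taxa=tuple(taxa), values=np.array(rows))
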