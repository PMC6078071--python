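"""Distance-based tree reconstruction: Poisson-corrected protein distances,
neighbor joining and nonparametric bootstrap supports.

This is the desk-scale stand-in for external ML/Bayesian inference: the
classifier consumes its newick output exactly as it would consume trees
from heavyweight tools.  Bootstrap supports are written into the MLBP slot
only; the BPP slot is left absent (an NJ bootstrap is not a posterior).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import GAP, MSA
from .trees import GeneTree, Node, SupportPair

log = logging.getLogger(__name__)

N_STATES = 20
SATURATION_P = (N_STATES - 1) / N_STATES  # 0.95

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "p_distance",
    "poisson_correct",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
]


class SaturationError(ValueError):
    """Observed mismatch proportion at or beyond the model's ceiling."""


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray
    saturated: np.ndarray  # boolean mask, same shape as d

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.saturated.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.diag(self.d) == 0):
            raise ValueError("diagonal must be zero")

    @property
    def has_saturation(self) -> bool:
        return bool(self.saturated.any())

    def to_phylip(self) -> str:
        lines = [f"{len(self.ids)}"]
        for i, name in enumerate(self.ids):
            vals = " ".join(f"{x:.8f}" for x in self.d[i])
            lines.append(f"{name:<12s}{vals}")
        return "\n".join(lines) + "\n"


def p_distance(msa: MSA, i: str, j: str) -> tuple[float, int]:
    """Mismatch proportion over pairwise gap-free columns.

    Returns ``(p, n_compared)``; raises when no column is comparable.
    """
    a, b = msa[i], msa[j]
    compared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError(f"no comparable (gap-free) columns between {i!r} and {j!r}")
    return mismatches / compared, compared


def poisson_correct(p: float) -> float:
    """Invert the expected-mismatch curve of the Poisson amino-acid model:
    ``d = -(19/20) ln(1 - 20 p / 19)``."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= SATURATION_P:
        raise SaturationError(
            f"p = {p:.4f} >= {SATURATION_P}; distance undefined (saturated)"
        )
    k = N_STATES
    return -(k - 1) / k * math.log(1.0 - k * p / (k - 1))


def _encoded(msa: MSA, ids: Sequence[str]) -> np.ndarray:
    """Rows as a byte matrix for vectorized column comparisons."""
    return np.frombuffer(
        "".join(msa[i] for i in ids).encode("ascii"), dtype=np.uint8
    ).reshape(len(ids), msa.length)


def _distance_arrays(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise Poisson-corrected distances from a byte matrix.

    Returns ``(d, saturated)``; raises when a pair shares no gap-free column.
    """
    valid = mat != ord(GAP)
    pair_valid = valid[:, None, :] & valid[None, :, :]
    compared = pair_valid.sum(axis=-1)
    mismatch = ((mat[:, None, :] != mat[None, :, :]) & pair_valid).sum(axis=-1)
    np.fill_diagonal(compared, 1)  # self-comparisons are zero anyway
    if (compared == 0).any():
        raise ValueError("a sequence pair shares no comparable (gap-free) column")
    p = mismatch / compared
    saturated = p >= SATURATION_P
    k = N_STATES
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -(k - 1) / k * np.log(1.0 - k * np.where(saturated, 0.0, p) / (k - 1))
    d[saturated] = np.nan
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(saturated, False)
    return d, saturated


def distance_matrix(msa: MSA, ids: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """All pairwise Poisson-corrected distances; saturated pairs flagged."""
    ids = tuple(ids if ids is not None else msa.ids)
    d, saturated = _distance_arrays(_encoded(msa, ids))
    return DistanceMatrix(ids, d, saturated)


def neighbor_joining(dm: DistanceMatrix) -> GeneTree:
    """Standard neighbor joining (Q-criterion, Studier–Keppler updates).

    Deterministic: Q-ties are broken on the lexicographically smallest pair
    of cluster representatives (the minimal tip name in each cluster).
    Negative branch-length estimates are clamped to zero with the deficit
    logged.  The returned tree is unrooted (trifurcating root), supports
    unset.
    """
    if dm.has_saturation:
        raise SaturationError("distance matrix has saturated entries")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[Node] = [Node(name=name) for name in dm.ids]
    reps: list[str] = list(dm.ids)  # tie-break representative per cluster
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(value: float, where: str) -> float:
        if value < 0:
            log.debug("clamped negative branch length %.6g at %s", value, where)
            return 0.0
        return value

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # candidate pairs within a tiny tolerance of the minimum
        cand = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            (tuple(sorted((reps[active[a]], reps[active[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, f"join({reps[i]},{reps[j]})")
        lj = clamp(lj, f"join({reps[i]},{reps[j]})")
        nodes[i].length = li
        nodes[j].length = lj
        new_node = Node(children=[nodes[i], nodes[j]])
        # Studier–Keppler update for distances to the new cluster
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new_node)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # closed-form resolution of the final three clusters
    a, b, c = active
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]), "final-a")
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]), "final-b")
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]), "final-c")
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    order = sorted((a, b, c), key=lambda k: reps[k])
    return GeneTree(Node(children=[nodes[k] for k in order]))


def nj_from_msa(msa: MSA) -> GeneTree:
    return neighbor_joining(distance_matrix(msa))


def bootstrap_support(
    msa: MSA, B: int, seed: int, warn_skip_fraction: float = 0.10
) -> GeneTree:
    """NJ point tree with nonparametric bootstrap supports on internal edges.

    Columns are resampled with replacement ``B`` times; each replicate is
    rebuilt with NJ and the fraction of replicates containing each point-tree
    bipartition is written into the MLBP slot (percent).  Replicates whose
    distance matrix saturates are skipped and counted; a warning is issued
    when more than ``warn_skip_fraction`` of replicates were skipped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    ids = tuple(msa.ids)
    encoded = _encoded(msa, ids)
    point = neighbor_joining(distance_matrix(msa, ids))

    counts: dict[frozenset[str], int] = {s: 0 for s in point.bipartitions()}
    length = msa.length
    skipped = 0
    successful = 0
    for _ in range(B):
        cols = rng.integers(0, length, size=length)
        try:
            d, saturated = _distance_arrays(encoded[:, cols])
            if saturated.any():
                raise SaturationError("saturated replicate")
            rep_tree = neighbor_joining(
                DistanceMatrix(ids, d, saturated)
            )
        except (SaturationError, ValueError):
            skipped += 1
            continue
        successful += 1
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if skipped > warn_skip_fraction * B:
        warnings.warn(
            f"{skipped} of {B} bootstrap replicates skipped (saturation)",
            stacklevel=2,
        )
    denom = max(successful, 1)

    all_tips = frozenset(ids)
    anchor = min(all_tips)
    clades = point.clades()
    for node in point.iter_nodes():
        if node is point.root or node.is_leaf:
            continue
        below = clades[node]
        side = all_tips - below if anchor in below else below
        if side in counts:
            node.support = SupportPair(mlbp=100.0 * counts[side] / denom)
    return point
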