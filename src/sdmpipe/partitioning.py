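"""Train/test partitioning: checkerboard blocks or random K-fold.

Species with 15 or more presence records get a geographically
structured checkerboard split whose block size is optimized over a
candidate range by three simultaneous criteria — minimal spatial
autocorrelation (Moran's I), maximal environmental similarity between
folds (Euclidean distance between standardized fold centroids), and
minimal imbalance of record counts (SD) — aggregated by rank sum.
Species with fewer records get a random K-fold split (k=3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .occurrences import LabeledPoints

__all__ = [
    "BlockDiagnostics",
    "moran_i",
    "checkerboard_assign",
    "optimize_block_size",
    "kfold_assign",
    "assign_folds",
]


@dataclass
class BlockDiagnostics:
    """Criterion values for one candidate checkerboard block size."""

    block_size: float
    moran_i: float
    env_distance: float
    count_sd: float
    valid: bool = True
    ranks: tuple[float, float, float] | None = None

    @property
    def rank_sum(self) -> float:
        return float("inf") if self.ranks is None else sum(self.ranks)


def moran_i(
    values: np.ndarray,
    coords: np.ndarray,
    weight_scheme: str = "inverse_distance",
    max_dist: float | None = None,
    spacing: float = 1.0,
) -> float:
    """Classical Moran's I spatial autocorrelation statistic.

    I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with ``w_ii = 0``. ``weight_scheme`` is ``"inverse_distance"``
    (optionally truncated beyond ``max_dist``) or ``"rook"`` (unit
    weights between lattice neighbors one ``spacing`` apart).
    """
    values = np.asarray(values, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = values.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 points")
    dev = values - values.mean()
    denom = np.sum(dev**2)
    if denom == 0:
        raise ValueError("Moran's I is undefined for constant values")

    d = cdist(coords, coords)
    if weight_scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = np.where(d > 0, 1.0 / d, 0.0)
        if max_dist is not None:
            w[d > max_dist] = 0.0
    elif weight_scheme == "rook":
        dx = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        dy = np.abs(coords[:, 1][:, None] - coords[:, 1][None, :])
        eps = 1e-9 * spacing
        w = (
            ((np.abs(dx - spacing) < eps) & (dy < eps))
            | ((np.abs(dy - spacing) < eps) & (dx < eps))
        ).astype(float)
    else:
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    np.fill_diagonal(w, 0.0)
    W = w.sum()
    if W == 0:
        raise ValueError("weight matrix is all zero; points too far apart?")
    num = dev @ w @ dev
    return float((n / W) * num / denom)


def checkerboard_assign(
    coords: np.ndarray,
    block_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Two-fold checkerboard labels: parity of the containing block."""
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    bx = np.floor((coords[:, 0] - origin[0]) / block_size).astype(int)
    by = np.floor((coords[:, 1] - origin[1]) / block_size).astype(int)
    return ((bx + by) % 2).astype(int)


def _split_criteria(
    points: LabeledPoints, folds: np.ndarray, block_size: float
) -> BlockDiagnostics:
    n0, n1 = int(np.sum(folds == 0)), int(np.sum(folds == 1))
    if n0 == 0 or n1 == 0:
        return BlockDiagnostics(block_size, np.nan, np.nan, np.nan, valid=False)
    try:
        I = moran_i(
            points.labels.astype(float),
            points.coords,
            weight_scheme="inverse_distance",
            max_dist=5.0 * block_size,
        )
    except ValueError:
        return BlockDiagnostics(block_size, np.nan, np.nan, np.nan, valid=False)

    X = points.env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    centroid0 = Z[folds == 0].mean(axis=0)
    centroid1 = Z[folds == 1].mean(axis=0)
    env_dist = float(np.linalg.norm(centroid0 - centroid1))
    count_sd = float(np.std([n0, n1]))
    return BlockDiagnostics(block_size, I, env_dist, count_sd, valid=True)


def optimize_block_size(
    points: LabeledPoints,
    candidates: np.ndarray,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, list[BlockDiagnostics]]:
    """Choose the checkerboard block size by three-criterion rank sum.

    For each candidate, folds are assigned and three criteria computed
    (lower is better for all: Moran's I of the presence/absence labels,
    Euclidean distance between fold environmental centroids, SD of fold
    record counts). Each criterion is ranked across valid candidates and
    the candidate with the smallest rank sum wins; ties break to the
    smallest block size.
    """
    if points.env is None:
        raise ValueError("points carry no environmental values")
    candidates = np.sort(np.unique(np.asarray(candidates, dtype=float)))
    if candidates.size < 1:
        raise ValueError("no candidate block sizes")
    diags = [
        _split_criteria(points, checkerboard_assign(points.coords, b, origin), b)
        for b in candidates
    ]
    valid = [d for d in diags if d.valid]
    if not valid:
        raise ValueError(
            "every candidate block size left an empty fold; use the K-fold split instead"
        )
    for crit in ("moran_i", "env_distance", "count_sd"):
        vals = np.array([getattr(d, crit) for d in valid])
        ranks = rankdata(vals, method="average")
        for d, r in zip(valid, ranks):
            d.ranks = (r,) if d.ranks is None else d.ranks + (r,)
    best = min(valid, key=lambda d: (d.rank_sum, d.block_size))
    return best.block_size, diags


def kfold_assign(n: int, k: int = 3, seed: int = 0) -> np.ndarray:
    """Random K-fold labels with balanced fold sizes (⌊n/k⌋ or ⌈n/k⌉)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def assign_folds(
    points: LabeledPoints,
    candidates: np.ndarray,
    min_checkerboard: int = 15,
    k: int = 3,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[LabeledPoints, dict]:
    """Checkerboard split for data-rich species, K-fold otherwise.

    The checkerboard path is taken iff the (post-thinning) presence
    count is at least ``min_checkerboard``; its block size is optimized
    over ``candidates``. Returns the points with a fold column plus a
    dict describing the chosen partition.
    """
    n_pres = int(np.sum(points.labels == 1))
    if n_pres >= min_checkerboard:
        try:
            block, diags = optimize_block_size(points, candidates, origin)
            folds = checkerboard_assign(points.coords, block, origin)
            info = {"method": "checkerboard", "block_size": block, "diagnostics": diags}
            return replace(points, folds=folds), info
        except ValueError:
            pass  # all candidates invalid: fall through to K-fold
    folds = kfold_assign(points.n, k=k, seed=seed)
    return replace(points, folds=folds), {"method": "kfold", "k": k}
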