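"""Model evaluation (Jaccard, rank AUC), threshold selection, ensembling.

Continuous predictions are evaluated on held-out test points with the
Jaccard similarity index TP/(TP+FP+FN) — computed at the threshold that
maximizes it — and the threshold-independent AUC of the ROC curve. The
ensemble takes a simple average of the per-algorithm suitability maps,
keeping only algorithms whose evaluation score exceeds the across-
algorithm mean; the max-Jaccard threshold then binarizes the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .raster import RasterGrid

__all__ = [
    "EvaluationRecord",
    "EnsembleResult",
    "confusion",
    "jaccard",
    "auc",
    "max_jaccard_threshold",
    "build_ensemble",
    "binarize",
]


@dataclass
class EvaluationRecord:
    species_id: str
    algorithm_id: str
    fold: int
    jaccard: float
    auc: float
    threshold: float


@dataclass
class EnsembleResult:
    """Above-mean ensemble of per-algorithm suitability maps."""

    species_id: str
    scenario_id: str
    member_ids: list[str]
    mean_score: float
    map: RasterGrid
    threshold: float | None = None
    binary_map: RasterGrid | None = None


def confusion(pred_binary: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) counts of binary predictions against labels."""
    pred = np.asarray(pred_binary).astype(bool)
    obs = np.asarray(labels).astype(bool)
    if pred.size == 0:
        raise ValueError("empty test set")
    if pred.shape != obs.shape:
        raise ValueError("predictions and labels are not aligned")
    tp = int(np.sum(pred & obs))
    fp = int(np.sum(pred & ~obs))
    fn = int(np.sum(~pred & obs))
    tn = int(np.sum(~pred & ~obs))
    return tp, fp, fn, tn


def jaccard(tp: int, fp: int, fn: int) -> float:
    """Jaccard similarity TP / (TP + FP + FN)."""
    denom = tp + fp + fn
    if denom == 0:
        raise ValueError("Jaccard undefined: TP + FP + FN = 0")
    return tp / denom


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(presence score > absence score), ties count 1/2.

    Equals the normalized Mann–Whitney U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes in the test set")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def max_jaccard_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """The observed score maximizing Jaccard of (score >= threshold).

    Candidates are the unique observed scores; ties break to the lowest
    such threshold. Returns ``(threshold, jaccard_at_threshold)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("threshold selection needs both classes")
    best_t, best_j = np.nan, -1.0
    for t in np.unique(scores):  # ascending: first max is the lowest threshold
        pred = scores >= t
        tp, fp, fn, _ = confusion(pred, labels)
        j = jaccard(tp, fp, fn)
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t, best_j


def build_ensemble(
    maps: dict[str, RasterGrid],
    scores: dict[str, float],
    species_id: str = "",
    scenario_id: str = "present",
) -> EnsembleResult:
    """Average the maps of algorithms scoring above the across-algorithm mean.

    If no algorithm strictly exceeds the mean (all scores equal), every
    algorithm is kept.
    """
    if not maps:
        raise ValueError("no algorithm maps to ensemble")
    if set(maps) != set(scores):
        raise ValueError("maps and scores name different algorithms")
    cutoff = float(np.mean(list(scores.values())))
    members = [a for a in maps if scores[a] > cutoff]
    if not members:
        members = list(maps)
    grids = [maps[a] for a in members]
    for g in grids[1:]:
        grids[0].require_aligned(g, "member map")
    mean_map = grids[0].with_values(np.mean([g.values for g in grids], axis=0))
    return EnsembleResult(
        species_id=species_id,
        scenario_id=scenario_id,
        member_ids=members,
        mean_score=cutoff,
        map=mean_map,
    )


def binarize(suitability: RasterGrid, threshold: float) -> RasterGrid:
    """Presence (1) where suitability >= threshold, absence (0) below; nodata kept."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    v = suitability.values
    out = np.where(np.isnan(v), np.nan, (v >= threshold).astype(float))
    return suitability.with_values(out)
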