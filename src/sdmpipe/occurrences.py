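"""Occurrence records: thinning and environmentally restricted pseudo-absences.

Occurrences are thinned to one record per coarse grid cell (twice the
predictor resolution by default) to reduce geographic sampling bias,
and pseudo-absences are drawn at a 1:1 ratio with presences from cells
falling *outside* the presences' environmental envelope, so the
"absence" class carries real environmental signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .raster import ClimateStack, RasterGrid

__all__ = [
    "PRESENCE",
    "PSEUDO_ABSENCE",
    "LabeledPoints",
    "Envelope",
    "extract_env",
    "thin",
    "fit_envelope",
    "sample_pseudo_absences",
]

PRESENCE = 1
PSEUDO_ABSENCE = 0


@dataclass
class LabeledPoints:
    """Point records for one species: coordinates, class labels, folds, env values."""

    species_id: str
    coords: np.ndarray  # (n, 2) of x, y
    labels: np.ndarray  # (n,) of {PRESENCE, PSEUDO_ABSENCE}
    folds: np.ndarray | None = None
    env: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.coords.shape[0] != self.labels.shape[0]:
            raise ValueError("coords and labels must have equal length")
        if not set(np.unique(self.labels)) <= {PRESENCE, PSEUDO_ABSENCE}:
            raise ValueError("labels must be presence (1) or pseudo-absence (0)")
        if self.env is not None and len(self.env) != len(self.labels):
            raise ValueError("env row count must equal point count")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    def subset(self, idx: np.ndarray) -> "LabeledPoints":
        return LabeledPoints(
            species_id=self.species_id,
            coords=self.coords[idx],
            labels=self.labels[idx],
            folds=None if self.folds is None else self.folds[idx],
            env=None if self.env is None else self.env.iloc[idx].reset_index(drop=True),
        )

    def presences(self) -> "LabeledPoints":
        return self.subset(np.nonzero(self.labels == PRESENCE)[0])

    @staticmethod
    def concat(parts: list["LabeledPoints"]) -> "LabeledPoints":
        if not parts:
            raise ValueError("nothing to concatenate")
        env = None
        if all(p.env is not None for p in parts):
            env = pd.concat([p.env for p in parts], ignore_index=True)
        folds = None
        if all(p.folds is not None for p in parts):
            folds = np.concatenate([p.folds for p in parts])
        return LabeledPoints(
            species_id=parts[0].species_id,
            coords=np.vstack([p.coords for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            folds=folds,
            env=env,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "species": self.species_id,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "label": self.labels,
            }
        )
        if self.folds is not None:
            df["fold"] = self.folds
        if self.env is not None:
            df = pd.concat([df, self.env.reset_index(drop=True)], axis=1)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @staticmethod
    def from_csv(path) -> "LabeledPoints":
        df = pd.read_csv(path)
        base = {"species", "x", "y", "label", "fold"}
        env_cols = [c for c in df.columns if c not in base]
        return LabeledPoints(
            species_id=str(df["species"].iloc[0]) if len(df) else "unknown",
            coords=df[["x", "y"]].to_numpy(),
            labels=df["label"].to_numpy(),
            folds=df["fold"].to_numpy() if "fold" in df else None,
            env=df[env_cols].reset_index(drop=True) if env_cols else None,
        )


@dataclass
class Envelope:
    """Rectilinear (min–max, BIOCLIM-style) environmental envelope."""

    variable_names: list[str]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower > self.upper):
            raise ValueError("envelope lower bounds exceed upper bounds")

    def contains(self, X: np.ndarray) -> np.ndarray:
        """True for rows with every variable inside [lower, upper]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.all((X >= self.lower) & (X <= self.upper), axis=1)


def extract_env(points: LabeledPoints, stack: ClimateStack) -> LabeledPoints:
    """Attach predictor values at each point's containing cell."""
    vals = stack.values_at(points.x, points.y)
    env = pd.DataFrame(vals, columns=stack.names)
    return replace(points, env=env)


def thin(
    points: LabeledPoints,
    cell_size: float,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LabeledPoints:
    """Keep at most one record per thinning cell, chosen uniformly at random.

    ``cell_size`` defaults in the pipeline to twice the predictor
    resolution, which removes dense clusters of records collected at the
    same locality. Idempotent under the same seed schedule.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    cx = np.floor((points.x - origin[0]) / cell_size).astype(int)
    cy = np.floor((points.y - origin[1]) / cell_size).astype(int)
    rng = np.random.default_rng(seed)
    keep = []
    groups: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(cx, cy)):
        groups.setdefault(key, []).append(i)
    for key in sorted(groups):
        members = groups[key]
        keep.append(members[rng.integers(len(members))])
    return points.subset(np.array(sorted(keep), dtype=int))


def fit_envelope(presences: LabeledPoints) -> Envelope:
    """Per-variable [min, max] over presence environmental values."""
    pres = presences.subset(np.nonzero(presences.labels == PRESENCE)[0])
    if pres.env is None:
        raise ValueError("presences carry no environmental values; run extract_env first")
    if pres.n < 1:
        raise ValueError("need at least one presence to fit an envelope")
    X = pres.env.to_numpy(dtype=float)
    return Envelope(
        variable_names=list(pres.env.columns),
        lower=X.min(axis=0),
        upper=X.max(axis=0),
    )


def sample_pseudo_absences(
    presences: LabeledPoints,
    env_stack: ClimateStack,
    envelope: Envelope,
    ratio: float = 1.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
    inside: bool = False,
) -> LabeledPoints:
    """Draw pseudo-absences among cells outside the environmental envelope.

    Exactly ``ratio`` pseudo-absences per presence (default 1:1), placed
    at cell centers, never on presence cells, sampled uniformly without
    replacement among eligible cells (with replacement, with a warning,
    only if eligible cells run short). With ``inside=True`` the
    restriction inverts: points are drawn among envelope-suitable cells
    instead.
    """
    pres = presences.subset(np.nonzero(presences.labels == PRESENCE)[0])
    n_needed = int(round(ratio * pres.n))
    X, rows, cols = env_stack.to_table(envelope.variable_names, mask=mask)
    in_env = envelope.contains(X)
    eligible = in_env if inside else ~in_env

    pr, pc = env_stack.grid.cell_of(pres.x, pres.y)
    pres_cells = set(zip(pr.tolist(), pc.tolist()))
    not_presence = np.array([(r, c) not in pres_cells for r, c in zip(rows, cols)])
    eligible &= not_presence

    pool = np.nonzero(eligible)[0]
    if pool.size == 0:
        raise ValueError(
            "no eligible cell for pseudo-absence sampling; relax the environmental "
            "envelope or enlarge the study area"
        )
    rng = np.random.default_rng(seed)
    if pool.size >= n_needed:
        chosen = rng.choice(pool, size=n_needed, replace=False)
    else:
        warnings.warn(
            f"only {pool.size} eligible cells for {n_needed} pseudo-absences; "
            "sampling with replacement",
            stacklevel=2,
        )
        chosen = rng.choice(pool, size=n_needed, replace=True)
    x, y = env_stack.grid.xy_of(rows[chosen], cols[chosen])
    env = pd.DataFrame(X[chosen], columns=envelope.variable_names)
    return LabeledPoints(
        species_id=presences.species_id,
        coords=np.column_stack([x, y]),
        labels=np.full(n_needed, PSEUDO_ABSENCE, dtype=int),
        env=env,
    )
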