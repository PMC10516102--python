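"""Orthogonal climate axes via PCA on standardized present-day layers.

The 19 bioclimatic variables are strongly collinear and mix units
(temperature in °C, precipitation in mm), so models are fit on the
leading principal components of the *correlation* matrix — the smallest
set of axes explaining at least 95% of total variance. Future climates
are projected with the coefficients (means, sds, loadings) estimated on
present data, so present and future scores live in one space.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .raster import ClimateStack, RasterGrid

__all__ = ["ClimatePCA"]


class ClimatePCA(BaseEstimator, TransformerMixin):
    """PCA transform from climate layers to score layers.

    Parameters
    ----------
    variance_threshold : float, default 0.95
        Keep the smallest number of axes whose cumulative explained
        variance reaches this fraction.

    Attributes
    ----------
    variable_names_ : list of str
        Layer names, in fitting order.
    means_, sds_ : ndarray
        Per-variable standardization constants from the present data.
    loadings_ : ndarray, (variables, axes)
        Orthonormal loading columns; the largest-magnitude entry of each
        column is forced positive for backend-independent signs.
    explained_ : ndarray
        Per-axis explained variance fractions (all axes, non-increasing).
    n_axes_ : int
        Number of retained axes.
    """

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    # ------------------------------------------------------------------
    def fit(self, present: ClimateStack, mask: np.ndarray | None = None) -> "ClimatePCA":
        """Fit on standardized cell values of `present` inside `mask`."""
        X, _, _ = present.to_table(mask=mask)
        if X.shape[0] < 2:
            raise ValueError("mask leaves fewer than 2 cells to fit the PCA on")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 layers")
        names = present.names
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        constant = [n for n, s in zip(names, sds) if s == 0 or not np.isfinite(s)]
        if constant:
            raise ValueError(f"constant layer(s) cannot be standardized: {constant}")

        Z = (X - means) / sds
        pca = PCA(svd_solver="full")
        pca.fit(Z)
        loadings = pca.components_.T  # (variables, axes)
        # sign convention: largest-magnitude loading of each axis positive
        for j in range(loadings.shape[1]):
            i = np.argmax(np.abs(loadings[:, j]))
            if loadings[i, j] < 0:
                loadings[:, j] = -loadings[:, j]
        explained = pca.explained_variance_ratio_
        n_axes = int(np.searchsorted(np.cumsum(explained), self.variance_threshold - 1e-12) + 1)

        self.variable_names_ = names
        self.means_ = means
        self.sds_ = sds
        self.loadings_ = loadings
        self.explained_ = explained
        self.n_axes_ = n_axes
        return self

    @property
    def axis_names_(self) -> list[str]:
        return [f"pc{j + 1}" for j in range(self.n_axes_)]

    # ------------------------------------------------------------------
    def transform(self, stack: ClimateStack) -> ClimateStack:
        """Project any stack into the fitted space (present coefficients).

        Cells that are nodata in any input layer are nodata in every
        score layer.
        """
        missing = [n for n in self.variable_names_ if n not in stack]
        if missing:
            raise KeyError(f"stack '{stack.scenario}' is missing variables: {missing}")
        sub = stack.subset(self.variable_names_)
        grid = sub.grid
        X, rows, cols = sub.to_table()
        scores = ((X - self.means_) / self.sds_) @ self.loadings_[:, : self.n_axes_]
        layers = {}
        for j, name in enumerate(self.axis_names_):
            vals = np.full(grid.shape, np.nan)
            vals[rows, cols] = scores[:, j]
            layers[name] = grid.with_values(vals)
        return ClimateStack(layers, scenario=stack.scenario)

    def fit_transform(self, present: ClimateStack, mask: np.ndarray | None = None) -> ClimateStack:
        return self.fit(present, mask=mask).transform(present)

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "variable_names": self.variable_names_,
            "means": self.means_.tolist(),
            "sds": self.sds_.tolist(),
            "loadings": self.loadings_.tolist(),
            "explained": self.explained_.tolist(),
            "n_axes": self.n_axes_,
            "variance_threshold": self.variance_threshold,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClimatePCA":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        obj = cls(variance_threshold=doc["variance_threshold"])
        obj.variable_names_ = list(doc["variable_names"])
        obj.means_ = np.asarray(doc["means"])
        obj.sds_ = np.asarray(doc["sds"])
        obj.loadings_ = np.asarray(doc["loadings"])
        obj.explained_ = np.asarray(doc["explained"])
        obj.n_axes_ = int(doc["n_axes"])
        return obj
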