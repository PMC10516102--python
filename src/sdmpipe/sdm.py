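"""The five suitability algorithms behind one sklearn-style estimator.

``SDMClassifier`` wraps GLM (binomial regression with linear and
quadratic terms), a MaxEnt-like penalized logistic model for presence
vs background, random forest, a probability-calibrated SVM, and a
Gaussian-process classifier. All predict habitat suitability in [0, 1]
and are deterministic under their seed; default hyperparameters are
fixed rather than tuned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.svm import SVC

from .raster import ClimateStack, RasterGrid

__all__ = ["ALGORITHMS", "SDMClassifier", "fit_algorithm", "predict_map"]

#: The five algorithm identifiers.
ALGORITHMS = ("glm", "maxent_like", "rf", "svm", "gau")


def _add_squares(X):
    X = np.asarray(X, dtype=float)
    return np.hstack([X, X**2])


class SDMClassifier(BaseEstimator, ClassifierMixin):
    """One of the five suitability algorithms, selected by id.

    Parameters
    ----------
    algorithm : {"glm", "maxent_like", "rf", "svm", "gau"}
        glm — unpenalized binomial regression on linear + quadratic
        terms; maxent_like — L2-penalized logistic on the same feature
        expansion, intended for presence-vs-background data (the
        penalized-logistic equivalent of MaxEnt's exponential model);
        rf — random forest (bagged trees); svm — RBF support-vector
        classifier with probability calibration; gau — Gaussian-process
        classifier with an RBF kernel.
    seed : int
        Seed for every stochastic learner.
    """

    def __init__(self, algorithm: str = "glm", seed: int = 0):
        self.algorithm = algorithm
        self.seed = seed

    def _build(self):
        quad = FunctionTransformer(_add_squares)
        if self.algorithm == "glm":
            return Pipeline(
                [
                    ("quad", quad),
                    ("scale", StandardScaler()),
                    ("clf", LogisticRegression(C=np.inf, max_iter=2000)),
                ]
            )
        if self.algorithm == "maxent_like":
            return Pipeline(
                [
                    ("quad", quad),
                    ("scale", StandardScaler()),
                    ("clf", LogisticRegression(C=1.0, max_iter=2000)),
                ]
            )
        if self.algorithm == "rf":
            return RandomForestClassifier(n_estimators=200, random_state=self.seed)
        if self.algorithm == "svm":
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", SVC(kernel="rbf", probability=True, random_state=self.seed)),
                ]
            )
        if self.algorithm == "gau":
            kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", GaussianProcessClassifier(kernel=kernel, random_state=self.seed)),
                ]
            )
        raise ValueError(
            f"unknown algorithm {self.algorithm!r}; valid ids: {', '.join(ALGORITHMS)}"
        )

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "SDMClassifier":
        """Fit on presence (1) / absence-or-background (0) data."""
        if isinstance(X, pd.DataFrame):
            self.predictor_names_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.predictor_names_ = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class; cannot fit")
        self.model_ = self._build()
        self.model_.fit(X, y)
        self.classes_ = classes
        return self

    def predict_suitability(self, X) -> np.ndarray:
        """Continuous suitability (probability of presence) in [0, 1]."""
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names_].to_numpy(dtype=float)
        proba = self.model_.predict_proba(np.asarray(X, dtype=float))[:, -1]
        return np.clip(proba, 0.0, 1.0)

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names_].to_numpy(dtype=float)
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_suitability(X) >= 0.5).astype(int)

    # ------------------------------------------------------------------
    def predict_map(self, stack: ClimateStack) -> RasterGrid:
        """Suitability raster over a climate stack; nodata propagated."""
        missing = [n for n in self.predictor_names_ if n not in stack]
        if missing:
            raise KeyError(f"stack '{stack.scenario}' lacks predictors: {missing}")
        X, rows, cols = stack.to_table(self.predictor_names_)
        out = np.full(stack.grid.shape, np.nan)
        if rows.size:
            out[rows, cols] = self.predict_suitability(X)
        return stack.grid.with_values(out)


def fit_algorithm(algorithm: str, X, y, seed: int = 0) -> SDMClassifier:
    """Functional wrapper: fit one algorithm and return the estimator."""
    return SDMClassifier(algorithm=algorithm, seed=seed).fit(X, y)


def predict_map(fit: SDMClassifier, stack: ClimateStack) -> RasterGrid:
    """Functional wrapper over :meth:`SDMClassifier.predict_map`."""
    return fit.predict_map(stack)
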