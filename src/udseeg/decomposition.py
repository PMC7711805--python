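"""Variance-threshold PCA over the per-channel feature space.

Features are centered but not standardized (all columns are SampEn values
on a common dimensionless scale), projected onto the orthonormal directions
of maximal variance, and the smallest leading set of components whose
cumulative explained-variance ratio reaches the threshold (default 95 %)
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import FeatureMatrix

__all__ = ["PCAModel", "fit_pca", "transform"]

_EPS = 1e-9  # tolerance on the cumulative-ratio comparison


@dataclass
class PCAModel:
    """Fitted principal-component model.

    ``loadings`` holds one orthonormal component per row (all components,
    descending explained variance); ``n_retained`` is the smallest k whose
    cumulative ``explained_ratio`` reaches ``threshold``.
    """

    center: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_ratio: np.ndarray
    n_retained: int
    threshold: float

    @property
    def retained_cumulative_ratio(self) -> float:
        return float(self.explained_ratio[: self.n_retained].sum())


def fit_pca(features: FeatureMatrix | np.ndarray, threshold: float = 0.95) -> PCAModel:
    """Fit PCA and apply the cumulative-variance retention rule.

    Component signs are fixed by making each loading's largest-magnitude
    element positive, so repeated fits are reproducible.  A zero-variance
    (constant) input has no principal directions and raises.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("input has zero variance; PCA is undefined")

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.copy()
    for i, row in enumerate(loadings):
        if row[np.argmax(np.abs(row))] < 0:
            loadings[i] = -row
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    n_retained = int(np.searchsorted(cum, threshold - _EPS) + 1)
    n_retained = min(n_retained, len(ratio))
    return PCAModel(
        center=pca.mean_.copy(),
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        explained_ratio=ratio.copy(),
        n_retained=n_retained,
        threshold=threshold,
    )


def transform(model: PCAModel, features: FeatureMatrix | np.ndarray):
    """Project onto the retained components (scores on the fitted basis).

    Accepts a bare array (returns an array) or a FeatureMatrix (returns a
    FeatureMatrix with score columns PC1..PCk and metadata carried over).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.shape[1] != model.center.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} != model dimension {model.center.shape[0]}"
        )
    scores = (X - model.center) @ model.loadings[: model.n_retained].T
    if not isinstance(features, FeatureMatrix):
        return scores
    return FeatureMatrix(
        scores,
        features.labels,
        [f"PC{i + 1}" for i in range(model.n_retained)],
        features.participant_ids,
    )
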