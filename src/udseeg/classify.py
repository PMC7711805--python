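"""Classifier configurations and stratified 10-fold cross-validated evaluation.

Six configurations are benchmarked: KNN (Euclidean metric, squared-inverse
distance weights, k selectable in 2..10), a Gini decision tree capped at 20
splits, unpenalized logistic regression, and polynomial-kernel SVMs of
degree 1 (linear), 2 (quadratic) and 3 (cubic).  Each trained model exposes
hard labels and a continuous UDS-oriented score so ROC curves can be drawn
for every classifier.

Cross-validation is stratified by class; optionally the PCA reduction is
refit inside each training fold (leakage-free default), fit once globally,
or skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .containers import FeatureMatrix
from .decomposition import PCAModel, fit_pca, transform
from .metrics import ConfusionMatrix, MetricSet, ROCCurve, compute_metrics, roc_auc
from .profiles import UDS

__all__ = [
    "ClassifierSpec",
    "CVConfig",
    "CVResult",
    "TrainedClassifier",
    "train_classifier",
    "run_cv",
    "select_knn_k",
    "DEFAULT_CLASSIFIERS",
]

_KINDS = ("knn", "dt", "lr", "svm_linear", "svm_quadratic", "svm_cubic")

#: The benchmark suite in reporting order.
DEFAULT_CLASSIFIERS = _KINDS


def _squared_inverse(dists: np.ndarray) -> np.ndarray:
    """KNN vote weight 1/d^2, with exact hits dominating finitely."""
    d = np.maximum(dists, 1e-12)
    return 1.0 / (d * d)


@dataclass(frozen=True)
class ClassifierSpec:
    """One benchmark configuration.

    Only the parameters the benchmark fixes are exposed: the KNN metric is
    Euclidean with squared-inverse weights, the tree uses the Gini
    diversity index with at most ``dt_max_splits`` splits, SVM kernels are
    polynomial of the degree implied by ``kind`` with box constraint
    ``regularization``, unit kernel offset and inverse-variance ("scale")
    kernel scaling, and the logistic regression is unpenalized.
    """

    kind: str
    knn_k: int = 3
    dt_max_splits: int = 20
    regularization: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "knn" and not 2 <= self.knn_k <= 10:
            raise ValueError("knn_k must lie in [2, 10]")
        if self.dt_max_splits < 1:
            raise ValueError("dt_max_splits must be >= 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")

    @property
    def svm_degree(self) -> int:
        return {"svm_linear": 1, "svm_quadratic": 2, "svm_cubic": 3}[self.kind]

    def build(self):
        if self.kind == "knn":
            return KNeighborsClassifier(
                n_neighbors=self.knn_k,
                metric="euclidean",
                weights=_squared_inverse,
            )
        if self.kind == "dt":
            return DecisionTreeClassifier(
                criterion="gini",
                max_leaf_nodes=self.dt_max_splits + 1,
                random_state=0,
            )
        if self.kind == "lr":
            # C=inf disables the ridge penalty (plain maximum likelihood)
            return LogisticRegression(C=np.inf, max_iter=2000)
        return SVC(
            kernel="poly",
            degree=self.svm_degree,
            C=self.regularization,
            gamma="scale",
            coef0=1.0,
        )


@dataclass
class TrainedClassifier:
    """Fitted model exposing labels and a continuous UDS score per row."""

    spec: ClassifierSpec
    estimator: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=object)

    def score_uds(self, X: np.ndarray) -> np.ndarray:
        """Larger = more UDS-like: probability (KNN/DT/LR) or SVM decision value."""
        est = self.estimator
        pos = list(est.classes_).index(UDS)
        if isinstance(est, SVC):
            df = est.decision_function(X)
            return df if pos == 1 else -df
        return est.predict_proba(X)[:, pos]


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y) -> TrainedClassifier:
    """Fit one configuration; both classes must appear in ``y``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if len(np.unique(y.astype(str))) < 2:
        raise ValueError("training data must contain both classes")
    est = spec.build()
    est.fit(X, y.astype(str))
    return TrainedClassifier(spec, est)


@dataclass
class CVConfig:
    """Cross-validation settings (fold count, stratification, seed, PCA placement)."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    pca_mode: str = "off"            # per_fold | global | off
    pca_threshold: float = 0.95
    by_participant: bool = False     # group folds by participant id

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.pca_mode not in ("per_fold", "global", "off"):
            raise ValueError(f"unknown pca_mode {self.pca_mode!r}")


@dataclass
class CVResult:
    """Per-fold and pooled outcomes of one classifier under k-fold CV."""

    spec: ClassifierSpec
    config: CVConfig
    fold_confusions: list[ConfusionMatrix]
    fold_metrics: list[MetricSet]
    pooled_confusion: ConfusionMatrix
    pooled_metrics: MetricSet
    roc: ROCCurve
    fold_assignment: np.ndarray          # fold index per row
    fold_pca_centers: list[np.ndarray]   # empty unless pca_mode == per_fold
    global_pca: PCAModel | None = None

    @property
    def pooled_accuracy(self) -> float:
        return self.pooled_metrics.acc


def _folds(y: np.ndarray, config: CVConfig, groups: np.ndarray | None = None):
    if config.by_participant:
        if groups is None:
            raise ValueError("participant-grouped CV needs participant ids")
        splitter = StratifiedGroupKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        return splitter.split(np.zeros(len(y)), y.astype(str), groups)
    cls = StratifiedKFold if config.stratified else KFold
    splitter = cls(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    return splitter.split(np.zeros(len(y)), y.astype(str))


def run_cv(features: FeatureMatrix, spec: ClassifierSpec, config: CVConfig) -> CVResult:
    """Evaluate one classifier under seeded (stratified) k-fold CV.

    Fold test sets partition the rows; the pooled confusion matrix is the
    sum over folds, and the ROC curve is computed from the pooled
    out-of-fold scores.  With ``pca_mode="per_fold"`` the reduction is fit
    on each training split only, so no test information reaches the model.
    """
    X, y = features.values, features.labels
    _, counts = np.unique(y.astype(str), return_counts=True)
    if config.stratified and counts.min() < config.n_folds:
        raise ValueError("need at least n_folds rows per class for stratified CV")

    global_model: PCAModel | None = None
    if config.pca_mode == "global":
        global_model = fit_pca(X, config.pca_threshold)

    fold_assignment = np.full(len(y), -1, dtype=int)
    oof_scores = np.empty(len(y))
    fold_cms: list[ConfusionMatrix] = []
    fold_ms: list[MetricSet] = []
    centers: list[np.ndarray] = []
    for f, (tr, te) in enumerate(_folds(y, config, features.participant_ids)):
        Xtr, Xte = X[tr], X[te]
        if config.pca_mode == "per_fold":
            pca = fit_pca(Xtr, config.pca_threshold)
            centers.append(pca.center.copy())
            Xtr, Xte = transform(pca, Xtr), transform(pca, Xte)
        elif config.pca_mode == "global":
            Xtr, Xte = transform(global_model, Xtr), transform(global_model, Xte)
        model = train_classifier(spec, Xtr, y[tr])
        pred = model.predict(Xte)
        oof_scores[te] = model.score_uds(Xte)
        fold_assignment[te] = f
        cm = ConfusionMatrix.from_labels(y[te], pred)
        fold_cms.append(cm)
        fold_ms.append(compute_metrics(cm))

    pooled = sum(fold_cms[1:], fold_cms[0])
    return CVResult(
        spec=spec,
        config=config,
        fold_confusions=fold_cms,
        fold_metrics=fold_ms,
        pooled_confusion=pooled,
        pooled_metrics=compute_metrics(pooled),
        roc=roc_auc(oof_scores, y),
        fold_assignment=fold_assignment,
        fold_pca_centers=centers,
        global_pca=global_model,
    )


def select_knn_k(
    features: FeatureMatrix,
    config: CVConfig,
    candidates: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10),
) -> tuple[int, dict[int, float]]:
    """Pick the KNN neighborhood size maximizing pooled CV accuracy.

    All candidates are evaluated under the same seeded folds; ties break
    toward the smaller k.  Returns (best_k, accuracy per candidate).
    """
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    accs: dict[int, float] = {}
    for k in candidates:
        res = run_cv(features, ClassifierSpec("knn", knn_k=k), config)
        accs[k] = res.pooled_accuracy
    best = max(sorted(accs), key=lambda k: accs[k])  # sorted => ties to smaller k
    return best, accs
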