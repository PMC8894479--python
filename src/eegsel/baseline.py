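"""Classical-classifier harness: SVM / naive Bayes / kNN on DWT features.

One model per subject, stratified k-fold cross-validation (k = 10, shrunk when
a subject has fewer instances), internal model selection over a small grid
(SVM kernels sigmoid/linear/rbf; kNN 1-9 neighbors; NB has no grid), selected
by cross-validated accuracy on the same folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import adjust_kfold

FAMILIES = ("svm", "nb", "knn")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to fit and the grid it may search."""

    family: str
    svm_kernels: tuple[str, ...] = ("sigmoid", "linear", "rbf")
    svm_C: tuple[float, ...] = (0.1, 1.0, 10.0)
    knn_neighbors: tuple[int, ...] = tuple(range(1, 10))

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")


@dataclass
class CVReport:
    """Cross-validated accuracy of one subject's model."""

    mean_accuracy: float
    sd: float
    chosen_params: dict[str, Any] = field(default_factory=dict)
    k_used: int = 10
    family: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


def _estimator_and_grid(spec: ClassifierSpec, max_neighbors: int):
    if spec.family == "svm":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", SVC(gamma="scale"))])
        grid = {"clf__kernel": list(spec.svm_kernels), "clf__C": list(spec.svm_C)}
    elif spec.family == "knn":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", KNeighborsClassifier())])
        ks = [k for k in spec.knn_neighbors if k <= max_neighbors]
        grid = {"clf__n_neighbors": ks or [1]}
    else:
        est = GaussianNB()
        grid = {}
    return est, grid


def crossval_classify(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                      k: int = 10, seed: int = 0) -> CVReport:
    """Stratified k-fold accuracy with internal grid selection.

    The grid point with the highest mean cross-validated accuracy is chosen;
    its fold mean/sd is reported (selection and reporting share the folds).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes")
    k_used = adjust_kfold(len(y), k)
    # a fold's training split must keep >= 1 neighbor available
    min_class = int(np.bincount(y).min())
    k_used = min(k_used, min_class) if min_class >= 2 else k_used
    cv = StratifiedKFold(n_splits=k_used, shuffle=True, random_state=seed)
    max_neighbors = max(1, len(y) - int(np.ceil(len(y) / k_used)))
    est, grid = _estimator_and_grid(spec, max_neighbors)
    if grid:
        search = GridSearchCV(est, grid, scoring="accuracy", cv=cv, n_jobs=1)
        search.fit(X, y)
        i = search.best_index_
        return CVReport(float(search.cv_results_["mean_test_score"][i]),
                        float(search.cv_results_["std_test_score"][i]),
                        dict(search.best_params_), k_used, spec.family)
    scores = cross_val_score(est, X, y, scoring="accuracy", cv=cv, n_jobs=1)
    return CVReport(float(scores.mean()), float(scores.std()), {}, k_used, spec.family)


def per_subject_summary(reports: list[CVReport]) -> tuple[float, float]:
    """Unweighted mean and sample sd (ddof=1) of per-subject mean accuracies."""
    if not reports:
        raise ValueError("no reports to summarize")
    accs = np.array([r.mean_accuracy for r in reports], dtype=float)
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return float(accs.mean()), sd
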