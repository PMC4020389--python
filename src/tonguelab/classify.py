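"""Cross-validated classification of group membership from V1..V7.

The seven histogram proportions are evaluated as a feature vector for
separating the two cohorts with three standard classifiers — Gaussian Naïve
Bayes, k-nearest neighbors, and a support-vector machine — under stratified
10-fold cross-validation.  Stratification matters: with a heavily imbalanced
cohort an unstratified fold can lose the minority class entirely.

Hyperparameters (k = 5 with Euclidean distance, RBF kernel with C = 1,
features standardized for KNN and SVM) are plain textbook defaults and are
all configurable through :class:`ClassifierSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import AnalysisError, ConfigError

__all__ = ["ClassifierSpec", "CVResult", "cv_accuracy"]

METHODS = ("naive_bayes", "knn", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    method: str = "naive_bayes"
    k: int = 5
    kernel: str = "rbf"
    cost: float = 1.0
    folds: int = 10
    seed: int = 0
    features: tuple[str, ...] = tuple(f"V{i}" for i in range(1, 8))

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.k < 1:
            raise ConfigError("k must be >= 1")

    def build(self):
        if self.method == "naive_bayes":
            return GaussianNB()
        if self.method == "knn":
            return make_pipeline(
                StandardScaler(), KNeighborsClassifier(n_neighbors=self.k)
            )
        return make_pipeline(
            StandardScaler(), SVC(kernel=self.kernel, C=self.cost)
        )


@dataclass(frozen=True)
class CVResult:
    accuracy: float
    fold_accuracies: tuple[float, ...]
    spec: ClassifierSpec
    n: int
    majority_fraction: float

    def as_dict(self) -> dict:
        return {
            "method": self.spec.method,
            "accuracy": self.accuracy,
            "fold_accuracies": list(self.fold_accuracies),
            "folds": self.spec.folds,
            "seed": self.spec.seed,
            "n": self.n,
            "majority_fraction": self.majority_fraction,
        }


def cv_accuracy(cohort: pd.DataFrame, spec: ClassifierSpec | None = None) -> CVResult:
    """Mean held-out accuracy under seeded stratified k-fold CV.

    Raises :class:`AnalysisError` if any class has fewer members than folds
    (the fold partition would be degenerate).
    """
    spec = spec or ClassifierSpec()
    X = cohort.loc[:, list(spec.features)].to_numpy(dtype=float)
    y = cohort["group"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise AnalysisError(f"expected two classes, found {list(classes)}")
    if counts.min() < spec.folds:
        raise AnalysisError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} members, "
            f"fewer than {spec.folds} folds"
        )
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    fold_acc = []
    for train, test in skf.split(X, y):
        clf = spec.build()
        clf.fit(X[train], y[train])
        fold_acc.append(float((clf.predict(X[test]) == y[test]).mean()))
    return CVResult(
        accuracy=float(np.mean(fold_acc)),
        fold_accuracies=tuple(fold_acc),
        spec=spec,
        n=len(y),
        majority_fraction=float(counts.max() / counts.sum()),
    )
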