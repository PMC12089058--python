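"""Classifier suite with a uniform fit/predict contract.

Six families are supported with fixed hyperparameter grids:

=========== ========================================== =============
family      grid                                        cardinality
=========== ========================================== =============
SVM_LINEAR  C in {0.1, 1, 10}                           3
KNN         k in {3, 5, 7, 9}                           4
LDA         (none)                                      1
QDA         regularisation in {0.1, 0.5, 1}             3
ANN         hidden layer in {10, 50}, max_iter 5000     2
RF          trees in {10, 50, 100, 200}                 4
=========== ========================================== =============

The real-time pipeline default is the linear SVM with C = 1, squared hinge
loss and at most 1000 iterations.  All estimators are scikit-learn; the
wrapper pins seeds so fits are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

SVM_LINEAR = "SVM_LINEAR"
KNN = "KNN"
LDA = "LDA"
QDA = "QDA"
ANN = "ANN"
RF = "RF"
FAMILIES = (SVM_LINEAR, KNN, LDA, QDA, ANN, RF)

#: hyperparameter grids, ascending so tie-breaks pick the smallest value
GRIDS: dict[str, dict[str, list]] = {
    SVM_LINEAR: {"C": [0.1, 1, 10]},
    KNN: {"n_neighbors": [3, 5, 7, 9]},
    LDA: {},
    QDA: {"reg_param": [0.1, 0.5, 1]},
    ANN: {"hidden_layer_size": [10, 50]},
    RF: {"n_estimators": [10, 50, 100, 200]},
}

#: real-time pipeline default (linear SVM, library defaults)
ONLINE_DEFAULT = {"family": SVM_LINEAR, "params": {"C": 1.0}}

ANN_MAX_ITER = 5000
SVM_MAX_ITER = 1000

#: class order: Visualization = 0, Workload = 1
CLASS_LABELS = ("A", "B")
LABEL_TO_CODE = {lab: i for i, lab in enumerate(CLASS_LABELS)}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def model_spec(family: str) -> ModelSpec:
    if family not in GRIDS:
        raise ValueError(f"unknown model family {family!r}")
    return ModelSpec(family, GRIDS[family])


def grid_iter(family: str) -> list[dict]:
    """Enumerate a family's grid as parameter dicts, ascending value order."""
    grid = GRIDS[family]
    if not grid:
        return [{}]
    (name, values), = grid.items()
    return [{name: v} for v in values]


def _make_estimator(family: str, params: dict, seed: int):
    if family == SVM_LINEAR:
        return LinearSVC(
            C=float(params.get("C", 1.0)),
            loss="squared_hinge",
            penalty="l2",
            max_iter=SVM_MAX_ITER,
            random_state=seed,
        )
    if family == KNN:
        return KNeighborsClassifier(
            n_neighbors=int(params.get("n_neighbors", 5)),
            weights="uniform",
            metric="euclidean",
        )
    if family == LDA:
        return LinearDiscriminantAnalysis()
    if family == QDA:
        return QuadraticDiscriminantAnalysis(reg_param=float(params.get("reg_param", 0.0)))
    if family == ANN:
        return MLPClassifier(
            hidden_layer_sizes=(int(params.get("hidden_layer_size", 10)),),
            activation="relu",
            solver="adam",
            max_iter=ANN_MAX_ITER,
            random_state=seed,
        )
    if family == RF:
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            criterion="gini",
            max_depth=None,
            random_state=seed,
        )
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class FittedModel:
    """A trained classifier plus the metadata needed to reproduce the fit."""

    family: str
    params: dict
    estimator: object
    seed: int
    n_train: int
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def fit(
    family: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    params: dict | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit one classifier; deterministic for a fixed seed."""
    X = np.asarray(X_train, float)
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    params = dict(params or {})
    est = _make_estimator(family, params, seed)
    with warnings.catch_warnings():
        # the capped-iteration linear SVM may stop before full convergence by design
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return FittedModel(
        family=family,
        params=params,
        estimator=est,
        seed=seed,
        n_train=X.shape[0],
        n_features=X.shape[1],
    )


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected [n, {model.n_features}] feature matrix, got {X.shape}"
        )
    return model.estimator.predict(X)
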