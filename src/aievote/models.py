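"""The five classifier families with their hyperparameter grids.

Each voter of the ensemble is one (classifier family, feature mode) pair.
The learners themselves are standard scikit-learn estimators; this module
owns the search grids, the inner stratified 5-fold selection, and a uniform
hard-label / positive-class-score interface on top of the fitted models.

Grid values follow the reference protocol where it states them:

* logistic regression — regularization strength spanning 1e-3 ... 1e3
  (7 log-spaced points);
* KNN — neighbors {3, 5, 7, 9, 11, 13, 15, 17, 18} (verbatim, including
  the even final value), Euclidean distance, uniform weights;
* gradient boosting — min samples split/leaf in 0.1 ... 0.5, max depth
  {3, 5, 7}, subsample {0.5, 0.75, 0.95};
* random forest — min samples split {2, 4}, estimators {10, 50, 100,
  200, 500};
* MLP — initial learning rate 1e-5 ... 1e-1 (5 log-spaced points),
  L2 penalty alpha {1e-5, 1e-4, 1e-3}, one hidden layer of 100 units.

Continuous ranges are discretized as noted; the ``reduced`` preset shrinks
every grid to at most two points per hyperparameter for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from aievote.dataio import ACQ, AIE

FAMILIES = ("logistic_regression", "knn", "gradient_boost", "random_forest", "mlp")

#: Fixed (non-searched) settings the reference protocol leaves unstated.
FIXED_PARAMS = {
    "logistic_regression": {"solver": "liblinear", "max_iter": 5000},
    "knn": {"metric": "euclidean", "weights": "uniform"},
    "gradient_boost": {"learning_rate": 0.1, "n_estimators": 50},
    "random_forest": {},
    "mlp": {"hidden_layer_sizes": (100,), "max_iter": 300, "early_stopping": False},
}

_FULL_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"C": list(np.logspace(-3, 3, 7))},
    "knn": {"n_neighbors": [3, 5, 7, 9, 11, 13, 15, 17, 18]},
    "gradient_boost": {
        "min_samples_split": [0.1, 0.2, 0.3, 0.4, 0.5],
        "min_samples_leaf": [0.1, 0.2, 0.3, 0.4, 0.5],
        "max_depth": [3, 5, 7],
        "subsample": [0.5, 0.75, 0.95],
    },
    "random_forest": {
        "min_samples_split": [2, 4],
        "n_estimators": [10, 50, 100, 200, 500],
    },
    "mlp": {
        "learning_rate_init": list(np.logspace(-5, -1, 5)),
        "alpha": [1e-5, 1e-4, 1e-3],
    },
}

_REDUCED_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"C": [0.1, 10.0]},
    "knn": {"n_neighbors": [5, 11]},
    "gradient_boost": {
        "min_samples_split": [0.2],
        "min_samples_leaf": [0.1],
        "max_depth": [3, 5],
        "subsample": [0.95],
    },
    "random_forest": {"min_samples_split": [2], "n_estimators": [50, 100]},
    "mlp": {"learning_rate_init": [1e-3, 1e-2], "alpha": [1e-4]},
}

GRID_PRESETS = {"full": _FULL_GRIDS, "reduced": _REDUCED_GRIDS}


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family and its hyperparameter search grid."""

    family: str
    grid: Mapping[str, Sequence]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty")

    def candidates(self) -> list[dict]:
        """Grid points in declared order (first key varies slowest)."""
        keys = list(self.grid)
        return [
            dict(zip(keys, values))
            for values in itertools.product(*(self.grid[k] for k in keys))
        ]


def build_grid(family: str, preset: str = "full") -> ClassifierSpec:
    """The search grid for one family; ``reduced`` shrinks it for desk scale."""
    if preset not in GRID_PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    grids = GRID_PRESETS[preset]
    if family not in grids:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return ClassifierSpec(family, {k: list(v) for k, v in grids[family].items()})


def make_estimator(family: str, params: Mapping, seed: int = 0):
    """Instantiate the scikit-learn estimator for one grid point."""
    kwargs = {**FIXED_PARAMS[family], **params}
    if family == "logistic_regression":
        return LogisticRegression(random_state=seed, **kwargs)
    if family == "knn":
        return KNeighborsClassifier(**kwargs)
    if family == "gradient_boost":
        return GradientBoostingClassifier(random_state=seed, **kwargs)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **kwargs)
    if family == "mlp":
        return MLPClassifier(random_state=seed, **kwargs)
    raise ValueError(f"unknown family {family!r}")


def encode_labels(y: Sequence[str]) -> np.ndarray:
    """Map AIE/ACQ labels to 1/0 with AIE positive."""
    arr = np.asarray(y)
    bad = set(arr) - {AIE, ACQ}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return (arr == AIE).astype(int)


def decode_labels(y01: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y01).astype(int) == 1, AIE, ACQ)


@dataclasses.dataclass
class TunedClassifier:
    """A fitted (family, mode) voter with its selected hyperparameters."""

    spec: ClassifierSpec
    mode: str
    chosen_params: dict
    fitted: object
    inner_cv_score: float
    seed: int

    @property
    def family(self) -> str:
        return self.spec.family


def tune_classifier(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: Sequence[str],
    inner_folds: int = 5,
    seed: int = 0,
    mode: str = "",
    scoring: str = "accuracy",
) -> TunedClassifier:
    """Exhaustive inner-CV grid search, then refit on all of (X, y).

    Selection score is mean stratified ``inner_folds``-fold accuracy (or F1
    on the positive class when ``scoring='f1'``).  Ties keep the earliest
    grid point, so results are reproducible for a fixed grid order.
    """
    X = np.asarray(X, dtype=np.float64)
    y01 = encode_labels(y)
    if X.shape[0] != y01.shape[0]:
        raise ValueError("X and y length mismatch")
    if len(np.unique(y01)) < 2:
        raise ValueError("need both classes present to tune a classifier")
    if X.shape[0] < inner_folds:
        raise ValueError("fewer samples than inner folds")
    if scoring not in ("accuracy", "f1"):
        raise ValueError(f"unknown scoring {scoring!r}")
    score_fn = accuracy_score if scoring == "accuracy" else (
        lambda t, p: f1_score(t, p, zero_division=0)
    )
    splitter = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y01))
    for _, val_idx in splits:
        if len(np.unique(y01[val_idx])) < 1:  # pragma: no cover - unreachable
            raise ValueError("degenerate inner fold")

    best_params: dict | None = None
    best_score = -np.inf
    for params in spec.candidates():
        fold_scores = []
        for train_idx, val_idx in splits:
            est = make_estimator(spec.family, params, seed)
            est.fit(X[train_idx], y01[train_idx])
            fold_scores.append(score_fn(y01[val_idx], est.predict(X[val_idx])))
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:  # strict: ties keep the earlier candidate
            best_score = mean_score
            best_params = params
    final = make_estimator(spec.family, best_params, seed)
    final.fit(X, y01)
    return TunedClassifier(spec, mode, dict(best_params), final, best_score, seed)


def predict_scores(model: TunedClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class (AIE) scores in [0, 1]."""
    X = np.asarray(X, dtype=np.float64)
    est = model.fitted
    if X.shape[1] != est.n_features_in_:
        raise ValueError(f"feature width {X.shape[1]} != trained {est.n_features_in_}")
    proba = est.predict_proba(X)
    pos_col = int(np.where(est.classes_ == 1)[0][0])
    return np.clip(proba[:, pos_col], 0.0, 1.0)


def predict_labels(model: TunedClassifier, X: np.ndarray) -> np.ndarray:
    """Hard AIE/ACQ labels; label = AIE iff score >= 0.5."""
    return decode_labels(predict_scores(model, X) >= 0.5)
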