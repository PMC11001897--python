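"""Stacking, bagging, and boosting classifiers over the 522-feature table.

Three families are supported:

* ``stacking`` — KNN, decision tree, ANN (multilayer perceptron) and
  RBF-SVM base learners whose out-of-fold predicted probabilities feed a
  gradient-boosting meta-learner (leakage-free 5-fold stacking).
* ``bagging`` — bagging classifier, random forest, extra trees, or a
  single decision tree.
* ``boosting`` — gradient boosting or histogram-based gradient boosting.

Distance/margin/gradient-descent learners (KNN, SVM, ANN) are wrapped in
a standardization pipeline fitted on training folds only; tree learners
are left unscaled. Every source of randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .encodings import FEATURE_COUNT, feature_names

MODEL_FORMAT_VERSION = "rna6ma-model-1"

FAMILIES: dict[str, tuple[str, ...]] = {
    "stacking": ("stacking",),
    "bagging": ("bagging-classifier", "random-forest", "extra-trees",
                "decision-tree"),
    "boosting": ("gradient-boost", "hist-gradient-boost"),
}

#: the headline configuration: the best-performing family/variant
DEFAULT_VARIANT = ("boosting", "gradient-boost")

# small documented grids, searched by 5-fold internal CV when tuning is on
TUNING_GRIDS: dict[str, dict[str, list[Any]]] = {
    "stacking": {
        "final_estimator__learning_rate": [0.05, 0.1, 0.2],
    },
    "bagging-classifier": {"n_estimators": [50, 100]},
    "random-forest": {"n_estimators": [100, 300],
                      "max_depth": [5, 10, None]},
    "extra-trees": {"n_estimators": [100, 300],
                    "max_depth": [5, 10, None]},
    "decision-tree": {"max_depth": [3, 5, 10, None]},
    "gradient-boost": {"learning_rate": [0.05, 0.1, 0.2],
                       "n_estimators": [100, 300]},
    "hist-gradient-boost": {"learning_rate": [0.05, 0.1, 0.2]},
}


@dataclass(frozen=True)
class ModelConfig:
    """Which ensemble to build, and how."""

    family: str = DEFAULT_VARIANT[0]
    variant: str | None = None
    seed: int = 0
    tuning: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILIES)}"
            )
        variant = self.variant or FAMILIES[self.family][0]
        if variant not in FAMILIES[self.family]:
            raise ValueError(
                f"variant {variant!r} not valid for family {self.family!r} "
                f"(options: {FAMILIES[self.family]})"
            )
        object.__setattr__(self, "variant", variant)


def _scaled(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


def build_estimator(config: ModelConfig):
    """Construct the (unfitted) scikit-learn estimator for a config."""
    seed = config.seed
    variant = config.variant
    if config.family == "stacking":
        base = [
            ("knn", _scaled(KNeighborsClassifier(n_neighbors=5))),
            ("dt", DecisionTreeClassifier(random_state=seed)),
            ("ann", _scaled(MLPClassifier(hidden_layer_sizes=(64,),
                                          max_iter=500,
                                          random_state=seed))),
            ("svm", _scaled(SVC(kernel="rbf", C=1.0, random_state=seed))),
        ]
        est = StackingClassifier(
            estimators=base,
            final_estimator=GradientBoostingClassifier(random_state=seed),
            cv=StratifiedKFold(5, shuffle=True, random_state=seed),
            stack_method="auto",  # predict_proba where available, else margin
        )
    elif variant == "bagging-classifier":
        est = BaggingClassifier(n_estimators=50, random_state=seed)
    elif variant == "random-forest":
        est = RandomForestClassifier(random_state=seed)
    elif variant == "extra-trees":
        est = ExtraTreesClassifier(random_state=seed)
    elif variant == "decision-tree":
        est = DecisionTreeClassifier(random_state=seed)
    elif variant == "gradient-boost":
        est = GradientBoostingClassifier(random_state=seed)
    elif variant == "hist-gradient-boost":
        est = HistGradientBoostingClassifier(random_state=seed)
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(variant)
    if config.tuning:
        est = GridSearchCV(
            est,
            TUNING_GRIDS[variant],
            cv=StratifiedKFold(5, shuffle=True, random_state=seed),
            scoring="accuracy",
            n_jobs=1,
        )
    return est


@dataclass
class TrainedEnsemble:
    """A fitted ensemble bound to the 522-name feature contract."""

    config: ModelConfig
    estimator: Any
    feature_names: list[str]
    metadata: dict[str, Any] = field(default_factory=dict)

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        cols = [c for c in features.columns if c not in ("id", "label")]
        if cols != self.feature_names:
            raise ValueError(
                "feature columns do not match the model's 522-name contract"
            )
        return features[cols].to_numpy(dtype=float)

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Per-sample probability of class 1 (6mA site)."""
        X = self._matrix(features)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def predict_calls(self, features: pd.DataFrame,
                      threshold: float = 0.5) -> np.ndarray:
        """Binary class calls at the given probability threshold."""
        return (self.predict_scores(features) >= threshold).astype(int)


def train(
    config: ModelConfig, features: pd.DataFrame, labels=None
) -> TrainedEnsemble:
    """Fit an ensemble on an encoded feature table.

    ``features`` is the table from :func:`rna6ma.encodings.encode_dataset`
    (a ``label`` column is used when ``labels`` is not given).
    """
    if labels is None:
        if "label" not in features.columns:
            raise ValueError("no labels given and no 'label' column present")
        labels = features["label"].to_numpy()
    y = np.asarray(labels, dtype=int)
    names = [c for c in features.columns if c not in ("id", "label")]
    if len(names) != FEATURE_COUNT or names != feature_names():
        raise ValueError(
            f"expected the {FEATURE_COUNT} standard feature columns"
        )
    X = features[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing or non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")

    est = build_estimator(config)
    est.fit(X, y)

    metadata: dict[str, Any] = {
        "n_samples": int(len(y)),
        "class_counts": {int(c): int(n) for c, n in zip(classes, counts)},
        "seed": config.seed,
    }
    if config.tuning:
        metadata["tuned_params"] = est.best_params_
        est = est.best_estimator_
    if config.family == "stacking":
        metadata["base_learners"] = [name for name, _ in est.estimators]
        metadata["meta_learner"] = type(est.final_estimator_).__name__
    return TrainedEnsemble(config, est, names, metadata)


def save(model: TrainedEnsemble, path) -> None:
    """Persist a fitted ensemble with its config and feature manifest."""
    joblib.dump(
        {
            "format": MODEL_FORMAT_VERSION,
            "config": model.config,
            "feature_names": model.feature_names,
            "metadata": model.metadata,
            "estimator": model.estimator,
        },
        path,
    )


def load(path) -> TrainedEnsemble:
    """Load a model written by :func:`save`, checking the format version."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format" not in payload:
        raise ValueError(f"{path} is not an rna6ma model file")
    if payload["format"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format {payload['format']!r} "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    return TrainedEnsemble(
        config=payload["config"],
        estimator=payload["estimator"],
        feature_names=payload["feature_names"],
        metadata=payload["metadata"],
    )
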