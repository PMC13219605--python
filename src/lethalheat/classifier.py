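"""Random-forest lethality classifier with Platt-scaled probabilities.

The raw ensemble score for an event is the fraction of trees voting
"lethal". Platt scaling maps that score through a logistic transformation
σ(a·s + b) fitted by maximum likelihood on a calibration set disjoint from
the forest's training data (the validation partition in the pipeline), and
a probability threshold (default 0.6) turns calibrated probabilities into
final labels. Ties at exactly the threshold classify as lethal —
under-prediction is the more damaging scenario for public health.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ForestHyperparams",
    "ForestModel",
    "CalibratedClassifier",
    "fit_forest",
    "raw_scores",
    "fit_platt",
    "predict_probability",
    "classify",
    "save_model",
    "load_model",
]

ARTIFACT_FORMAT_VERSION = 1


@dataclass
class ForestHyperparams:
    """Forest settings; imbalance is handled upstream by resampling, so no
    class weighting is applied here."""

    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ForestModel:
    """Fitted bootstrap-bagged tree ensemble plus training metadata."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    hyperparams: ForestHyperparams
    seed: int


@dataclass
class CalibratedClassifier:
    """Forest + Platt logistic map + decision threshold."""

    forest: ForestModel
    platt_a: float
    platt_b: float
    decision_threshold: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.forest.feature_names


def _check_features(X: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    return X.loc[:, list(names)].to_numpy(dtype=float)


def fit_forest(
    train_features: pd.DataFrame,
    train_labels: pd.Series | np.ndarray,
    hyperparams: ForestHyperparams | None = None,
    seed: int = 0,
) -> ForestModel:
    """Fit the ensemble; deterministic given the seed. Requires both
    classes in the training labels."""
    hp = hyperparams or ForestHyperparams()
    y = np.asarray(train_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; cannot fit")
    model = RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        max_features=hp.max_features,
        min_samples_leaf=hp.min_samples_leaf,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(train_features.to_numpy(dtype=float), y)
    return ForestModel(
        model=model,
        feature_names=tuple(train_features.columns),
        hyperparams=hp,
        seed=seed,
    )


def raw_scores(forest: ForestModel, X: pd.DataFrame) -> np.ndarray:
    """Fraction of trees voting lethal (hard per-tree votes, not averaged
    leaf probabilities)."""
    arr = _check_features(X, forest.feature_names)
    votes = np.zeros(len(arr))
    for tree in forest.model.estimators_:
        votes += tree.predict(arr)
    return votes / len(forest.model.estimators_)


def fit_platt(
    forest: ForestModel,
    calibration_features: pd.DataFrame,
    calibration_labels: pd.Series | np.ndarray,
    decision_threshold: float = 0.6,
) -> CalibratedClassifier:
    """Maximum-likelihood logistic fit of labels on raw forest scores.

    The calibration set must contain both classes and should be disjoint
    from the forest's training data, or calibration is biased.
    """
    y = np.asarray(calibration_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration labels contain a single class; cannot calibrate")
    s = raw_scores(forest, calibration_features).reshape(-1, 1)
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(s, y)
    return CalibratedClassifier(
        forest=forest,
        platt_a=float(lr.coef_[0, 0]),
        platt_b=float(lr.intercept_[0]),
        decision_threshold=decision_threshold,
    )


def predict_probability(clf: CalibratedClassifier, X: pd.DataFrame) -> np.ndarray:
    """Calibrated lethality probability σ(a·score + b) per event."""
    s = raw_scores(clf.forest, X)
    return 1.0 / (1.0 + np.exp(-(clf.platt_a * s + clf.platt_b)))


def classify(
    clf: CalibratedClassifier, X: pd.DataFrame, threshold: float | None = None
) -> np.ndarray:
    """Binary lethal labels: lethal iff probability >= threshold."""
    thr = clf.decision_threshold if threshold is None else threshold
    return (predict_probability(clf, X) >= thr).astype(int)


def save_model(clf: CalibratedClassifier, path) -> None:
    """Serialize the classifier with its metadata in a versioned container."""
    joblib.dump(
        {
            "format_version": ARTIFACT_FORMAT_VERSION,
            "model": clf.forest.model,
            "feature_names": list(clf.forest.feature_names),
            "hyperparams": clf.forest.hyperparams,
            "seed": clf.forest.seed,
            "platt_a": clf.platt_a,
            "platt_b": clf.platt_b,
            "decision_threshold": clf.decision_threshold,
        },
        path,
    )


def load_model(path) -> CalibratedClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != ARTIFACT_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model artifact version {payload.get('format_version')!r}"
        )
    forest = ForestModel(
        model=payload["model"],
        feature_names=tuple(payload["feature_names"]),
        hyperparams=payload["hyperparams"],
        seed=payload["seed"],
    )
    return CalibratedClassifier(
        forest=forest,
        platt_a=payload["platt_a"],
        platt_b=payload["platt_b"],
        decision_threshold=payload["decision_threshold"],
    )
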