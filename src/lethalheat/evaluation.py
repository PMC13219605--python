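"""Assessment of lethality classifiers under heavy class imbalance.

With 0.78% lethal prevalence, accuracy is nearly useless (predicting
"nonlethal" everywhere already scores 0.992), so assessment centres on
precision = TP/(TP+FP), recall = TP/(TP+FN) and their harmonic mean, the
F1 score. The module also provides the wet-bulb-temperature threshold
baseline, permutation and drop-column (retraining) feature importance,
greedy forward feature selection, and the predictor correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import (
    CalibratedClassifier,
    ForestHyperparams,
    classify,
    fit_forest,
    fit_platt,
)
from .features import stull_wbt
from .sampling import ResampleSpec, apply_resampling

__all__ = [
    "MetricsReport",
    "TrainingRecipe",
    "SelectionLadder",
    "compute_metrics",
    "wbt_threshold_classifier",
    "permutation_importance",
    "dropout_importance",
    "forward_selection",
    "feature_correlation",
    "tune_hyperparameters",
]


@dataclass
class MetricsReport:
    """Confusion counts plus the four headline fractions.

    Ratios with a zero denominator are reported as 0 and the affected
    metric names listed in ``undefined``, keeping metric ladders totally
    ordered instead of propagating NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "undefined": list(self.undefined),
        }


def compute_metrics(true_labels, predicted_labels) -> MetricsReport:
    """Accuracy, precision, recall and F1 from aligned binary vectors."""
    y = np.asarray(true_labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if y.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {y.shape} vs {p.shape}")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    undefined = []
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    if not total:
        undefined.append("accuracy")
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        undefined.append("precision")
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        undefined.append("recall")
    if precision > 0.0 and recall > 0.0:
        f1 = 2.0 / (1.0 / precision + 1.0 / recall)
    else:
        f1 = 0.0  # harmonic mean with a zero term vanishes in the limit
        if "precision" in undefined and "recall" in undefined:
            undefined.append("f1")
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        undefined=tuple(undefined),
    )


def wbt_threshold_classifier(
    events: pd.DataFrame, wbt_threshold: float
) -> tuple[np.ndarray, MetricsReport]:
    """Baseline that calls an event lethal iff its Stull wet-bulb
    temperature (from tmax_c and rh_mean_pct) reaches the threshold."""
    wbt = stull_wbt(
        events["tmax_c"].to_numpy(float), events["rh_mean_pct"].to_numpy(float)
    )
    pred = (np.asarray(wbt) >= wbt_threshold).astype(int)
    return pred, compute_metrics(events["lethal"].to_numpy(int), pred)


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------


def permutation_importance(
    clf: CalibratedClassifier,
    features: pd.DataFrame,
    labels,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and sd, over seeded repeats, of the F1 decrease when one
    feature column at a time is independently shuffled on held-out data."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = np.asarray(labels).astype(int)
    baseline = compute_metrics(y, classify(clf, features)).f1
    rng = np.random.default_rng(seed)
    rows = []
    for name in clf.feature_names:
        drops = []
        for _ in range(n_repeats):
            shuffled = features.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            drops.append(baseline - compute_metrics(y, classify(clf, shuffled)).f1)
        rows.append(
            {
                "feature": name,
                "mean_f1_decrease": float(np.mean(drops)),
                "sd_f1_decrease": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class TrainingRecipe:
    """Reproducible resample → fit → calibrate procedure over a feature
    subset, for retraining-based analyses (dropout importance, forward
    selection). SMOTE neighbours are re-fit in the active subspace."""

    X_train: pd.DataFrame
    y_train: pd.Series
    X_val: pd.DataFrame
    y_val: pd.Series
    resample: ResampleSpec = field(default_factory=ResampleSpec)
    hyperparams: ForestHyperparams = field(default_factory=ForestHyperparams)
    decision_threshold: float = 0.6
    seed: int = 0

    def train(self, feature_subset: list[str] | None = None) -> CalibratedClassifier:
        cols = list(feature_subset) if feature_subset is not None else list(
            self.X_train.columns
        )
        missing = [c for c in cols if c not in self.X_train.columns]
        if missing:
            raise KeyError(f"feature(s) not in training set: {missing}")
        Xr, yr = apply_resampling(self.X_train[cols], self.y_train, self.resample)
        forest = fit_forest(Xr, yr, self.hyperparams, seed=self.seed)
        return fit_platt(
            forest, self.X_val[cols], self.y_val, decision_threshold=self.decision_threshold
        )


def dropout_importance(
    recipe: TrainingRecipe,
    X_eval: pd.DataFrame,
    y_eval,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """F1 cost of removing each feature and retraining, on a fixed
    held-out set. Near-zero cost despite high permutation importance is
    the signature of correlated predictors."""
    all_feats = list(features) if features is not None else list(recipe.X_train.columns)
    y = np.asarray(y_eval).astype(int)
    full = recipe.train(all_feats)
    full_f1 = compute_metrics(y, classify(full, X_eval)).f1
    rows = []
    for name in all_feats:
        reduced = [f for f in all_feats if f != name]
        clf = recipe.train(reduced)
        f1 = compute_metrics(y, classify(clf, X_eval[reduced])).f1
        rows.append({"feature": name, "f1_decrease": full_f1 - f1})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionLadder:
    """Greedy forward-selection trace: at each step the remaining
    candidate whose addition maximises validation F1 joins the model; the
    recorded metrics are computed on the held-out test set."""

    steps: list[dict]
    candidates: tuple[str, ...]

    @property
    def selected(self) -> list[str]:
        return [s["feature"] for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps, start=1):
            m: MetricsReport = s["test_metrics"]
            rows.append(
                {
                    "step": i,
                    "feature": s["feature"],
                    "val_f1": s["val_f1"],
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
        return pd.DataFrame(rows).set_index("step")


def forward_selection(
    recipe: TrainingRecipe,
    X_test: pd.DataFrame,
    y_test,
    candidates: list[str] | None = None,
    max_steps: int | None = None,
) -> SelectionLadder:
    """Build the model one predictor at a time.

    The selection signal is validation F1 only (test data never guides the
    choice); ties break by candidate list order. Each step's chosen model
    is then scored on the test set for the ladder.
    """
    pool = list(candidates) if candidates is not None else list(recipe.X_train.columns)
    if not pool:
        raise ValueError("candidate feature list is empty")
    y_val = np.asarray(recipe.y_val).astype(int)
    y_tst = np.asarray(y_test).astype(int)
    chosen: list[str] = []
    steps: list[dict] = []
    n_steps = len(pool) if max_steps is None else min(max_steps, len(pool))
    for _ in range(n_steps):
        best_name, best_f1, best_clf = None, -1.0, None
        for name in pool:
            if name in chosen:
                continue
            trial = chosen + [name]
            clf = recipe.train(trial)
            f1 = compute_metrics(y_val, classify(clf, recipe.X_val[trial])).f1
            if f1 > best_f1:  # strict: ties keep the earlier candidate
                best_name, best_f1, best_clf = name, f1, clf
        chosen.append(best_name)
        test_metrics = compute_metrics(y_tst, classify(best_clf, X_test[chosen]))
        steps.append(
            {"feature": best_name, "val_f1": best_f1, "test_metrics": test_metrics}
        )
    return SelectionLadder(steps=steps, candidates=tuple(pool))


def tune_hyperparameters(
    recipe: TrainingRecipe,
    grid: list[ForestHyperparams],
) -> tuple[ForestHyperparams, pd.DataFrame]:
    """Seeded grid search over forest hyperparameters on the validation
    partition (the test set is never consulted). Returns the setting with
    the highest validation F1 (ties keep the earlier grid entry) and the
    full score table."""
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y_val = np.asarray(recipe.y_val).astype(int)
    rows = []
    best, best_f1 = None, -1.0
    for hp in grid:
        trial = TrainingRecipe(
            X_train=recipe.X_train, y_train=recipe.y_train,
            X_val=recipe.X_val, y_val=recipe.y_val,
            resample=recipe.resample, hyperparams=hp,
            decision_threshold=recipe.decision_threshold, seed=recipe.seed,
        )
        clf = trial.train()
        f1 = compute_metrics(y_val, classify(clf, recipe.X_val)).f1
        rows.append({"hyperparams": hp, "val_f1": f1})
        if f1 > best_f1:
            best, best_f1 = hp, f1
    return best, pd.DataFrame(rows)


def feature_correlation(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the predictors; zero-variance columns
    correlate 0 with everything (unit diagonal preserved)."""
    if len(features) < 2:
        raise ValueError("need at least 2 events to correlate features")
    corr = features.corr(method="pearson")
    zero_var = features.columns[features.std(ddof=0) == 0.0]
    for col in zero_var:
        corr.loc[col, :] = 0.0
        corr.loc[:, col] = 0.0
    np.fill_diagonal(corr.values, 1.0)
    corr.attrs["zero_variance"] = list(zero_var)
    return corr
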