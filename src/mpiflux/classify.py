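"""Balanced repeated cross-validation of pair classifiers.

Interaction gold standards are heavily imbalanced (many more non-interacting
than interacting pairs). The protocol therefore stratifies pairs into k
folds, and for each held-out fold trains on *all* positives of the remaining
folds plus an equal-size uniform random subset of their negatives, so every
training set is exactly balanced while the test fold keeps its natural
imbalance. Hyperparameters are tuned per training set by an inner
cross-validated grid search; the whole procedure is repeated with fresh fold
assignments, and metrics (AUC, AUPR, weighted F1, confusion counts) are
averaged over folds x repetitions.

One master seed drives every source of randomness through a counter-based
seed-spawning scheme, so identical configurations reproduce bit-identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import PairFeatureMatrix
from .labeling import LabelSet

__all__ = [
    "DEFAULT_GRIDS",
    "CVConfig",
    "CVResult",
    "compute_metrics",
    "balanced_cv",
    "feature_importance",
]

# Grid contents are this package's defaults and
# may be overridden per run.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "n_estimators": [100, 300],
        "max_depth": [None, 10],
        "min_samples_leaf": [1, 5],
    },
    "svm": {
        "clf__C": [0.1, 1.0, 10.0],
        "clf__kernel": ["rbf", "linear"],
    },
    "mlp": {
        "clf__hidden_layer_sizes": [(64,), (128, 64)],
        "clf__alpha": [1e-4, 1e-2],
    },
}


@dataclass
class CVConfig:
    model_kind: str = "rf"  # rf | svm | mlp
    folds: int = 5
    repetitions: int = 100
    grid: dict[str, list] | None = None  # None -> DEFAULT_GRIDS[model_kind]
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("rf", "svm", "mlp"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def resolved_grid(self) -> dict[str, list]:
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.model_kind]
        if not grid:
            raise ValueError("empty hyperparameter grid")
        return grid


@dataclass
class CVResult:
    model_kind: str
    per_fold: pd.DataFrame  # columns: repetition, fold, auc, aupr, f1_weighted, tp, fp, tn, fn
    chosen_params: list[dict]
    importances: pd.Series | None  # rf only, mean over folds, sums to 1
    feature_names: list[str]
    seed: int
    oof_scores: pd.DataFrame | None = None  # pair x repetition out-of-fold scores
    oof_predictions: pd.DataFrame | None = None

    @property
    def mean_auc(self) -> float:
        return float(self.per_fold["auc"].mean())

    @property
    def mean_aupr(self) -> float:
        return float(self.per_fold["aupr"].mean())

    @property
    def mean_f1(self) -> float:
        return float(self.per_fold["f1_weighted"].mean())

    def summary(self) -> dict:
        g = self.per_fold
        return {
            "model": self.model_kind,
            "auc_mean": self.mean_auc,
            "auc_sd": float(g["auc"].std(ddof=1)) if len(g) > 1 else 0.0,
            "aupr_mean": self.mean_aupr,
            "aupr_sd": float(g["aupr"].std(ddof=1)) if len(g) > 1 else 0.0,
            "f1_weighted_mean": self.mean_f1,
            "confusion_mean": {
                k: float(g[k].mean()) for k in ("tp", "fp", "tn", "fn")
            },
            "n_folds": int(g["fold"].nunique()),
            "n_repetitions": int(g["repetition"].nunique()),
            "seed": self.seed,
        }


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, predicted: np.ndarray | None = None
) -> dict:
    """AUC, AUPR, weighted F1 and confusion counts for one test fold.

    AUC is the Mann-Whitney rank statistic (ties credited 0.5); AUPR the
    step-wise precision-recall integral (average precision). ``predicted``
    defaults to thresholding the scores at 0.5, matching probabilistic
    outputs; callers with margin scores pass the model's native labels.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to compute AUC/AUPR")
    if predicted is None:
        predicted = (scores >= 0.5).astype(int)
    tn, fp, fn, tp = confusion_matrix(labels, predicted, labels=[0, 1]).ravel()
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1_weighted": float(f1_score(labels, predicted, average="weighted")),
        "tp": int(tp),
        "fp": int(fp),
        "tn": int(tn),
        "fn": int(fn),
    }


def _make_estimator(kind: str, seed: int):
    if kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if kind == "svm":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(random_state=seed))]
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                MLPClassifier(
                    random_state=seed,
                    max_iter=500,
                    learning_rate="adaptive",
                ),
            ),
        ]
    )


def _grid_size(grid: dict[str, list]) -> int:
    n = 1
    for vals in grid.values():
        n *= len(vals)
    return n


def _fit_tuned(kind, grid, X, y, seed, inner_folds):
    est = _make_estimator(kind, seed)
    if _grid_size(grid) == 1:
        params = {k: v[0] for k, v in grid.items()}
        est.set_params(**params)
        return est.fit(X, y), params
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, cv=inner, scoring="roc_auc", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


def _score_samples(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        try:
            return est.predict_proba(X)[:, 1]
        except AttributeError:
            pass
    return est.decision_function(X)


def balanced_cv(
    features: PairFeatureMatrix, labels: LabelSet, config: CVConfig
) -> CVResult:
    """Repeated stratified k-fold CV with balanced training sets.

    Only pairs present in both the feature matrix and the label set are
    used. Each repetition reshuffles the folds; within a repetition every
    labeled pair is tested exactly once.
    """
    keys = [f"{m}:{p}" for (m, p) in labels.labels]
    available = [k for k in keys if k in features.values.index]
    pair_index = [tuple(k.split(":", 1)) for k in available]
    y = np.array([labels.labels[p] for p in pair_index], dtype=int)
    X = features.values.loc[available].to_numpy(dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos < config.folds or n_neg < config.folds:
        raise ValueError(
            f"need at least {config.folds} pairs of each class "
            f"(have {n_pos} positives, {n_neg} negatives)"
        )
    grid = config.resolved_grid()

    records = []
    chosen: list[dict] = []
    importances_acc = np.zeros(X.shape[1])
    n_rf_fits = 0
    oof = np.full((len(y), config.repetitions), np.nan)
    oof_pred = np.full((len(y), config.repetitions), -1, dtype=int)

    for rep in range(config.repetitions):
        rep_seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(rep,))
        seeds = rep_seq.generate_state(2 * config.folds + 1) % (2**31)
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=int(seeds[0])
        )
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            pos_idx = train_idx[y[train_idx] == 1]
            neg_idx = train_idx[y[train_idx] == 0]
            rng = np.random.default_rng(int(seeds[1 + fold]))
            take = min(len(pos_idx), len(neg_idx))
            neg_sub = rng.choice(neg_idx, size=take, replace=False)
            bal_idx = np.concatenate([pos_idx, neg_sub])
            est, params = _fit_tuned(
                config.model_kind,
                grid,
                X[bal_idx],
                y[bal_idx],
                int(seeds[1 + config.folds + fold]),
                config.inner_folds,
            )
            scores = _score_samples(est, X[test_idx])
            predicted = est.predict(X[test_idx])
            metrics = compute_metrics(scores, y[test_idx], predicted=predicted)
            records.append(
                {
                    "repetition": rep,
                    "fold": fold,
                    **metrics,
                    "n_train_pos": int(len(pos_idx)),
                    "n_train_neg": int(len(neg_sub)),
                }
            )
            chosen.append(params)
            oof[test_idx, rep] = scores
            oof_pred[test_idx, rep] = predicted
            if config.model_kind == "rf":
                importances_acc += est.feature_importances_
                n_rf_fits += 1

    per_fold = pd.DataFrame.from_records(records)
    importances = None
    if config.model_kind == "rf" and n_rf_fits:
        imp = importances_acc / n_rf_fits
        total = imp.sum()
        if total > 0:
            imp = imp / total
        importances = pd.Series(imp, index=list(features.values.columns))
    pair_keys = [f"{m}:{p}" for (m, p) in pair_index]
    return CVResult(
        model_kind=config.model_kind,
        per_fold=per_fold,
        chosen_params=chosen,
        importances=importances,
        feature_names=list(features.values.columns),
        seed=config.seed,
        oof_scores=pd.DataFrame(oof, index=pair_keys),
        oof_predictions=pd.DataFrame(oof_pred, index=pair_keys),
    )


def feature_importance(result: CVResult) -> pd.Series:
    """Mean impurity-based importances of a Random-Forest CV run, ranked.

    Importances are averaged over all folds and repetitions and normalized
    to sum to one. A degenerate (all-zero) profile is returned as uniform
    with a note raised by the caller.
    """
    if result.model_kind != "rf" or result.importances is None:
        raise ValueError("feature importances are only defined for rf results")
    return result.importances.sort_values(ascending=False)
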