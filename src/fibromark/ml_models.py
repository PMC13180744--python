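"""Classifier evaluation under small-n regimes.

Implements the evaluation protocol for case/control classification on a
handful of samples: leave-one-out cross-validation with hyperparameters
tuned by internal stratified CV on each training fold (no leakage) and a
single ROC computed on the pooled held-out scores; recursive feature
elimination down to a top-k gene panel; nested stratified 3x3
cross-validation reporting mean +/- sd AUROC across outer folds; and a
label-permutation test in which the entire nested procedure is re-run on
shuffled labels, p = #{permuted statistic >= observed} / N.

Model families and default hyperparameter grids cover linear SVM, random
forest, AdaBoost, gradient boosting and extremely randomized trees.
Held-out scores are the positive-class probability where the family
provides one, else the decision function; the positive class is "case".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFE
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneOut,
    StratifiedKFold,
)
from sklearn.svm import SVC

from ._rng import component_rng, derive_seed

__all__ = [
    "CVConfig",
    "CVReport",
    "loocv_evaluate",
    "rfe_select",
    "nested_cv_evaluate",
    "permutation_test",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("svm", "random_forest", "adaboost", "gradient_boost", "extra_trees")

# Grids are small neighborhoods around the best reported settings
# (SVM C=1 gamma=0.001 linear; RF 500 trees min_leaf 4; AdaBoost lr 0.01
# n=50; GradientBoost lr 0.05 depth 2 n=100; ExtraTrees depth 10 min_leaf 2
# n=200).
DEFAULT_GRIDS: dict[str, dict] = {
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": [0.001], "kernel": ["linear"]},
    "random_forest": {"n_estimators": [200, 500], "min_samples_leaf": [2, 4]},
    "adaboost": {"n_estimators": [50, 100], "learning_rate": [0.01, 0.1]},
    "gradient_boost": {
        "n_estimators": [100],
        "learning_rate": [0.05, 0.1],
        "max_depth": [2],
    },
    "extra_trees": {"n_estimators": [200], "min_samples_leaf": [2], "max_depth": [10, None]},
}

_BEST_PARAMS: dict[str, dict] = {
    "svm": {"C": 1.0, "gamma": 0.001, "kernel": "linear"},
    "random_forest": {"n_estimators": 500, "min_samples_leaf": 4, "max_depth": None},
    "adaboost": {"n_estimators": 50, "learning_rate": 0.01},
    "gradient_boost": {"n_estimators": 100, "learning_rate": 0.05, "max_depth": 2},
    "extra_trees": {"n_estimators": 200, "min_samples_leaf": 2, "max_depth": 10},
}


@dataclass
class CVConfig:
    """Evaluation settings: model family, grid, fold counts, permutations."""

    model: str = "random_forest"
    grid: dict | None = None
    k_outer: int = 3
    k_inner: int = 3
    n_permutations: int = 1000
    top_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_FAMILIES:
            raise ValueError(f"model must be one of {MODEL_FAMILIES}")
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("k_outer and k_inner must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @property
    def effective_grid(self) -> dict:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.model]


@dataclass
class CVReport:
    mode: str
    auroc: float | None = None
    auprc: float | None = None
    fold_scores: list[float] = field(default_factory=list)
    mean_auroc: float | None = None
    sd_auroc: float | None = None
    selected_features: list[str] | None = None
    permutation_p: float | None = None
    predictions: pd.DataFrame | None = None  # pooled out-of-fold scores
    notes: dict = field(default_factory=dict)


def build_estimator(model: str, params: dict | None = None, seed: int = 0):
    """Instantiate a model family with given (or best-reported) params."""
    params = dict(_BEST_PARAMS[model] if params is None else params)
    if model == "svm":
        return SVC(random_state=seed, **params)
    if model == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if model == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if model == "gradient_boost":
        return GradientBoostingClassifier(random_state=seed, **params)
    if model == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown model {model!r}")


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str], list]:
    if isinstance(X, pd.DataFrame):
        feat_names = list(X.columns)
        sample_ids = list(X.index)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feat_names = [f"f{i}" for i in range(Xa.shape[1])]
        sample_ids = list(range(Xa.shape[0]))
    ya = np.asarray(y)
    if ya.dtype.kind in "OUS":
        ya = (ya == "case").astype(int)
    else:
        ya = ya.astype(int)
    if set(np.unique(ya)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    return Xa, ya, feat_names, sample_ids


def _score_samples(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, list(est.classes_).index(1)]
    return est.decision_function(X)


def _tuned_fit(Xtr, ytr, config: CVConfig, seed: int):
    """Grid search with internal stratified CV on the training data only."""
    inner = StratifiedKFold(
        n_splits=config.k_inner, shuffle=True, random_state=seed % (2**31)
    )
    gs = GridSearchCV(
        build_estimator(config.model, params=_first_point(config), seed=seed % (2**31)),
        param_grid=config.effective_grid,
        cv=inner,
        scoring="roc_auc",
        n_jobs=1,
        refit=True,
    )
    gs.fit(Xtr, ytr)
    return gs.best_estimator_, gs.best_params_


def _first_point(config: CVConfig) -> dict:
    return {k: v[0] for k, v in config.effective_grid.items()}


def loocv_evaluate(X, y, config: CVConfig) -> CVReport:
    """Leave-one-out CV with per-fold tuning and pooled-score AUROC/AUPRC.

    n folds, each holding out exactly one sample; hyperparameters tuned by
    stratified k_inner-fold CV inside each training fold; the single
    held-out score per fold is pooled and AUROC/AUPRC computed once on the
    pooled vector (one held-out sample admits no per-fold ROC).
    """
    Xa, ya, _, sample_ids = _as_xy(X, y)
    n = len(ya)
    if n < 4:
        raise ValueError(f"need >= 4 samples for LOOCV, got {n}")
    scores = np.empty(n)
    for k, (tr, te) in enumerate(LeaveOneOut().split(Xa)):
        if len(np.unique(ya[tr])) < 2:
            raise ValueError("a training fold lost a class entirely")
        est, _ = _tuned_fit(Xa[tr], ya[tr], config, derive_seed(config.seed, "loocv", k))
        scores[te[0]] = _score_samples(est, Xa[te])[0]
    predictions = pd.DataFrame(
        {"sample": sample_ids, "label": ya, "score": scores}
    ).set_index("sample")
    return CVReport(
        mode="loocv",
        auroc=float(roc_auc_score(ya, scores)),
        auprc=float(average_precision_score(ya, scores)),
        predictions=predictions,
        notes={"n_folds": n, "n_train_per_fold": n - 1},
    )


def rfe_select(X, y, config: CVConfig) -> list[str]:
    """Recursive feature elimination down to config.top_k features.

    Removes the least important feature one at a time (absolute linear
    coefficients for the linear SVM; impurity importances for the
    tree/boosting families); deterministic given the seed.
    """
    Xa, ya, feat_names, _ = _as_xy(X, y)
    if Xa.shape[1] < config.top_k:
        raise ValueError(
            f"top_k={config.top_k} exceeds feature count {Xa.shape[1]}"
        )
    if Xa.shape[1] == config.top_k:
        return feat_names
    est = build_estimator(config.model, seed=derive_seed(config.seed, "rfe"))
    selector = RFE(est, n_features_to_select=config.top_k, step=1)
    selector.fit(Xa, ya)
    return [f for f, keep in zip(feat_names, selector.support_) if keep]


def nested_cv_evaluate(X, y, config: CVConfig) -> CVReport:
    """Nested stratified CV: inner-grid tuning, outer-fold AUROC mean +/- sd."""
    Xa, ya, _, _ = _as_xy(X, y)
    counts = np.bincount(ya)
    if counts.min() < config.k_outer:
        raise ValueError(
            f"stratification infeasible: class counts {counts.tolist()} "
            f"< k_outer={config.k_outer}"
        )
    outer = StratifiedKFold(
        n_splits=config.k_outer,
        shuffle=True,
        random_state=derive_seed(config.seed, "outer"),
    )
    fold_scores = []
    for k, (tr, te) in enumerate(outer.split(Xa, ya)):
        est, _ = _tuned_fit(
            Xa[tr], ya[tr], config, derive_seed(config.seed, "nested", k)
        )
        fold_scores.append(float(roc_auc_score(ya[te], _score_samples(est, Xa[te]))))
    return CVReport(
        mode="nested",
        fold_scores=fold_scores,
        mean_auroc=float(np.mean(fold_scores)),
        sd_auroc=float(np.std(fold_scores, ddof=0)),
        notes={"k_outer": config.k_outer, "k_inner": config.k_inner},
    )


def permutation_test(
    X,
    y,
    config: CVConfig,
    observed_statistic: float,
    rule: str = "raw",
) -> tuple[float, np.ndarray]:
    """Label-permutation null for the nested-CV statistic.

    Shuffles class labels N times, repeats the full nested evaluation per
    shuffle (independent RNG substream each), and returns
    p = #{permuted >= observed} / N plus the permuted statistics.  The
    add-one rule (r+1)/(N+1) is available for conservatism.
    """
    if config.n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    if rule not in ("raw", "add_one"):
        raise ValueError("rule must be 'raw' or 'add_one'")
    Xa, ya, _, _ = _as_xy(X, y)
    stats_ = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        rng = component_rng(config.seed, "permutation", i)
        yp = rng.permutation(ya)
        perm_cfg = replace(config, seed=derive_seed(config.seed, "perm-eval", i))
        stats_[i] = nested_cv_evaluate(Xa, yp, perm_cfg).mean_auroc
    r = int((stats_ >= observed_statistic).sum())
    n = config.n_permutations
    p = r / n if rule == "raw" else (r + 1) / (n + 1)
    return float(p), stats_
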