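"""Nested-cross-validated classification of CHF / AF / healthy subjects.

The model is a fixed pipeline — per-feature min-max scaling, PCA, and a
gradient-boosted decision-tree ensemble (XGBoost) — evaluated with nested
cross-validation: 10 outer stratified random train/test splits with a 50%
test half, and 10-fold grid-search cross-validation *inside* each training
half for hyperparameter selection (optionally including the surface resize
sizes, in which case features are rebuilt per candidate).  Every fitted
transform sees training data only.

ROC AUC confidence intervals use DeLong's structural-components estimator.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from xgboost import XGBClassifier

__all__ = [
    "TaskSpec",
    "CVConfig",
    "FoldResult",
    "CVReport",
    "AUCResult",
    "DEFAULT_PARAM_GRID",
    "fit_model",
    "nested_cv",
    "metrics",
    "delong_auc",
]

#: Grid-search candidates used when the caller supplies none.
DEFAULT_PARAM_GRID: Dict[str, list] = {
    "pca__n_components": [10, 20, 50],
    "xgb__n_estimators": [100, 300],
    "xgb__max_depth": [2, 4, 6],
    "xgb__learning_rate": [0.05, 0.1],
}


@dataclass(frozen=True)
class TaskSpec:
    """What to classify: binary (with a positive class) or multiclass."""

    mode: str  # "binary" | "multiclass"
    classes: Tuple[str, ...]
    positive_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "multiclass"):
            raise ValueError("mode must be 'binary' or 'multiclass'")
        if self.mode == "binary":
            if len(self.classes) != 2 or self.positive_class not in self.classes:
                raise ValueError(
                    "binary tasks need exactly 2 classes and a positive_class"
                )
        elif len(self.classes) < 2:
            raise ValueError("multiclass tasks need >= 2 classes")


def _default_grid() -> Dict[str, list]:
    return {k: list(v) for k, v in DEFAULT_PARAM_GRID.items()}


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation parameters."""

    outer_folds: int = 10
    test_fraction: float = 0.5
    inner_folds: int = 10
    param_grid: Dict[str, list] = field(default_factory=_default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie strictly in (0, 1)")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("need >= 2 outer and inner folds")


@dataclass(frozen=True)
class FoldResult:
    confusion: np.ndarray  # (K, K), rows = true class
    sensitivity: Optional[float]
    specificity: Optional[float]
    balanced_accuracy: float
    chosen_params: dict
    test_indices: np.ndarray
    train_indices: np.ndarray


@dataclass(frozen=True)
class CVReport:
    """Per-fold and aggregate nested-CV results."""

    classes: Tuple[str, ...]
    per_fold: Tuple[FoldResult, ...]
    seed: int

    def _stat(self, attr: str) -> Tuple[Optional[float], Optional[float]]:
        vals = [getattr(f, attr) for f in self.per_fold]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None, None
        return float(np.mean(vals)), float(np.std(vals, ddof=1) if len(vals) > 1 else 0.0)

    @property
    def confusion_total(self) -> np.ndarray:
        return np.sum([f.confusion for f in self.per_fold], axis=0)

    @property
    def confusion_percent(self) -> np.ndarray:
        total = self.confusion_total.astype(float)
        rows = total.sum(axis=1, keepdims=True)
        return 100.0 * total / np.maximum(rows, 1.0)

    def to_dict(self) -> dict:
        mean_sens, sd_sens = self._stat("sensitivity")
        mean_spec, sd_spec = self._stat("specificity")
        mean_bacc, sd_bacc = self._stat("balanced_accuracy")
        return {
            "classes": list(self.classes),
            "seed": self.seed,
            "n_folds": len(self.per_fold),
            "mean_sensitivity": mean_sens,
            "sd_sensitivity": sd_sens,
            "mean_specificity": mean_spec,
            "sd_specificity": sd_spec,
            "mean_balanced_accuracy": mean_bacc,
            "sd_balanced_accuracy": sd_bacc,
            "confusion_total": self.confusion_total.tolist(),
            "confusion_percent": np.round(self.confusion_percent, 3).tolist(),
            "per_fold": [
                {
                    "confusion": f.confusion.tolist(),
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                    "balanced_accuracy": f.balanced_accuracy,
                    "chosen_params": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in f.chosen_params.items()
                    },
                }
                for f in self.per_fold
            ],
        }


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci95: Tuple[float, float]
    n_pos: int
    n_neg: int


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_model(
    train_features: np.ndarray,
    labels: np.ndarray,
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> Pipeline:
    """Fit min-max scaling -> PCA -> gradient-boosted trees on training data.

    ``labels`` are integer class codes.  PCA components exceeding the
    feasible maximum are capped with a warning.  Deterministic for a given
    seed.
    """
    hyperparams = dict(hyperparams or {})
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    n_comp = int(hyperparams.pop("pca__n_components", 20))
    cap = min(x.shape[0], x.shape[1])
    if n_comp > cap:
        warnings.warn(
            f"PCA components capped from {n_comp} to {cap} "
            f"(n_samples={x.shape[0]}, n_features={x.shape[1]})"
        )
        n_comp = cap
    xgb_params = {
        k.removeprefix("xgb__"): v
        for k, v in hyperparams.items()
        if k.startswith("xgb__")
    }
    model = Pipeline(
        [
            ("scale", MinMaxScaler(clip=False)),
            ("pca", PCA(n_components=n_comp, random_state=seed)),
            (
                "xgb",
                XGBClassifier(
                    n_estimators=int(xgb_params.get("n_estimators", 100)),
                    max_depth=int(xgb_params.get("max_depth", 4)),
                    learning_rate=float(xgb_params.get("learning_rate", 0.1)),
                    random_state=seed,
                    n_jobs=1,
                    # exact splits sit mid-gap between samples, which matters
                    # for generalization at cohort-sized n
                    tree_method="exact",
                    verbosity=0,
                ),
            ),
        ]
    )
    model.fit(x, y)
    return model


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _confusion(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> np.ndarray:
    c = np.zeros((k, k), dtype=int)
    np.add.at(c, (y_true, y_pred), 1)
    return c


def metrics(
    confusion: np.ndarray, task: TaskSpec
) -> Tuple[Optional[float], Optional[float], float]:
    """(sensitivity, specificity, balanced accuracy) from a confusion matrix.

    Rows are true classes in ``task.classes`` order.  Balanced accuracy is
    the mean of per-class recalls; classes with an empty row are excluded
    with a warning.  Sensitivity/specificity are reported for binary tasks
    only.
    """
    c = np.asarray(confusion, dtype=float)
    row_sums = c.sum(axis=1)
    recalls = []
    for i, total in enumerate(row_sums):
        if total == 0:
            warnings.warn(
                f"class {task.classes[i]!r} absent from evaluation; "
                "its recall is undefined and excluded"
            )
        else:
            recalls.append(c[i, i] / total)
    bacc = float(np.mean(recalls))
    if task.mode != "binary":
        return None, None, bacc
    p = task.classes.index(task.positive_class)
    n = 1 - p
    sens = c[p, p] / row_sums[p] if row_sums[p] > 0 else None
    spec = c[n, n] / row_sums[n] if row_sums[n] > 0 else None
    return (
        None if sens is None else float(sens),
        None if spec is None else float(spec),
        bacc,
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (ties get the average rank), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sorted_x = x[order]
    i = 0
    while i < x.size:
        j = i
        while j < x.size and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def delong_auc(scores: Sequence[float], labels: Sequence[int]) -> AUCResult:
    """ROC AUC with a DeLong 95% confidence interval.

    The AUC is the Mann-Whitney statistic (ties counted 1/2); the variance
    comes from the empirical variances of DeLong's structural components
    ``V10`` (per positive) and ``V01`` (per negative).  The interval is
    clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute an AUC")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n  # structural components of the positives
    v01 = 1.0 - (tz[m:] - ty) / m  # ... and of the negatives
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    lo = float(np.clip(auc - half, 0.0, 1.0))
    hi = float(np.clip(auc + half, 0.0, 1.0))
    return AUCResult(auc=float(auc), ci95=(lo, hi), n_pos=m, n_neg=n)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def nested_cv(
    features: Optional[np.ndarray],
    labels: Sequence[str],
    task: TaskSpec,
    cv: Optional[CVConfig] = None,
    feature_builder: Optional[Callable[[object], np.ndarray]] = None,
) -> CVReport:
    """Nested cross-validation of the scaling+PCA+boosted-trees pipeline.

    Parameters
    ----------
    features
        (n_subjects, n_features) matrix, or ``None`` when a
        ``feature_builder`` supplies candidate-dependent features.
    labels
        Per-subject class labels, drawn from ``task.classes``.
    task, cv
        Task definition and CV parameters.  ``cv.param_grid`` may contain a
        ``"resize"`` entry whose candidates are handed to
        ``feature_builder`` (features are rebuilt per candidate).
    """
    cv = cv or CVConfig()
    labels = np.asarray([str(l) for l in labels])
    classes = tuple(task.classes)
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in task classes {classes}")
    y = np.array([classes.index(l) for l in labels])
    k = len(classes)
    for i, cls in enumerate(classes):
        n_cls = int(np.count_nonzero(y == i))
        if n_cls < cv.inner_folds:
            raise ValueError(
                f"class {cls!r} has only {n_cls} subjects; "
                f"{cv.inner_folds} inner folds need at least that many"
            )

    grid = {key: list(vals) for key, vals in cv.param_grid.items()}
    resize_candidates = grid.pop("resize", [None])
    if resize_candidates != [None] and feature_builder is None:
        raise ValueError("a 'resize' grid requires a feature_builder")
    model_keys = sorted(grid)
    model_combos = [
        dict(zip(model_keys, combo))
        for combo in itertools.product(*(grid[k_] for k_ in model_keys))
    ] or [{}]

    feature_cache: Dict[object, np.ndarray] = {}

    def get_features(candidate) -> np.ndarray:
        if candidate is None:
            if features is None:
                raise ValueError("no feature matrix and no resize candidates")
            return np.asarray(features, dtype=float)
        if candidate not in feature_cache:
            feature_cache[candidate] = np.asarray(
                feature_builder(candidate), dtype=float
            )
        return feature_cache[candidate]

    outer = StratifiedShuffleSplit(
        n_splits=cv.outer_folds, test_size=cv.test_fraction, random_state=cv.seed
    )
    dummy = np.zeros((labels.size, 1))
    folds: List[FoldResult] = []
    for fold_idx, (train_idx, test_idx) in enumerate(outer.split(dummy, y)):
        inner = StratifiedKFold(
            n_splits=cv.inner_folds, shuffle=True, random_state=cv.seed + 1 + fold_idx
        )
        inner_splits = list(inner.split(dummy[train_idx], y[train_idx]))
        best_score, best_params, best_resize = -np.inf, {}, None
        for resize in resize_candidates:
            x_all = get_features(resize)
            x_train = x_all[train_idx]
            y_train = y[train_idx]
            for combo in model_combos:
                scores = []
                for itr, ival in inner_splits:
                    with warnings.catch_warnings():
                        # the cap resurfaces on the final refit; once is enough
                        warnings.filterwarnings(
                            "ignore", message="PCA components capped"
                        )
                        model = fit_model(
                            x_train[itr], y_train[itr], combo, seed=cv.seed
                        )
                    pred = model.predict(x_train[ival])
                    c = _confusion(y_train[ival], pred, k)
                    scores.append(metrics(c, task)[2])
                score = float(np.mean(scores))
                if score > best_score:
                    best_score, best_params, best_resize = score, dict(combo), resize
        x_all = get_features(best_resize)
        model = fit_model(x_all[train_idx], y[train_idx], best_params, seed=cv.seed)
        pred = model.predict(x_all[test_idx])
        confusion = _confusion(y[test_idx], pred, k)
        sens, spec, bacc = metrics(confusion, task)
        chosen = dict(best_params)
        if best_resize is not None:
            chosen["resize"] = best_resize
        folds.append(
            FoldResult(
                confusion=confusion,
                sensitivity=sens,
                specificity=spec,
                balanced_accuracy=bacc,
                chosen_params=chosen,
                test_indices=test_idx.copy(),
                train_indices=train_idx.copy(),
            )
        )
    return CVReport(classes=classes, per_fold=tuple(folds), seed=cv.seed)
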