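"""Balanced nested cross-validation over six classifier families.

The positive class (characterized pectinolytic enzymes) is heavily
outnumbered, so every training partition is rebalanced — by down-sampling the
majority, over-sampling the minority, or SMOTE interpolation — strictly inside
the fold before fitting.  Hyperparameters are tuned on an inner stratified CV
(default 5 folds), performance is estimated on an outer CV (default 3 folds)
whose test folds are never touched by balancing or tuning, and the final model
is refit on the whole balanced training set with the winning grid point.

Evaluation uses accuracy, specificity, recall, precision, F1 (all at a 0.5
score threshold) and the area under the precision–recall curve (average
precision).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FAMILIES = ("RF", "SVM", "GBM", "GLMnet", "kNN", "NB")

#: Compact per-family grid-search spaces (all configurable via ModelSpec).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [250, 500, 1000], "max_features": [0.1, 0.33, 0.5]},
    "SVM": {"C": [0.1, 1, 10], "gamma": ["scale", 0.01]},
    "GBM": {"max_depth": [2, 3], "learning_rate": [0.05, 0.1], "n_estimators": [100, 300]},
    "GLMnet": {"l1_ratio": [0.0, 0.5, 1.0], "C": [0.01, 0.1, 1.0, 10.0]},
    "kNN": {"n_neighbors": [3, 5, 7, 11]},
    "NB": {},
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        if not self.grid:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])

    def grid_points(self) -> list[dict]:
        keys = sorted(self.grid)
        if not keys:
            return [{}]
        return [dict(zip(keys, vals)) for vals in product(*(self.grid[k] for k in keys))]


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 3
    inner_folds: int = 5
    balancing: str = "down"
    inner_metric: str = "F1"  # or "PR_AUC"
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.balancing not in ("down", "over", "smote"):
            raise ValueError(f"unknown balancing method {self.balancing!r}")
        if self.inner_metric not in ("F1", "PR_AUC"):
            raise ValueError("inner_metric must be 'F1' or 'PR_AUC'")


def make_estimator(family: str, params: dict, seed: int):
    """A scikit-learn estimator for one grid point; scale-sensitive families
    (SVM, GLMnet, kNN) are wrapped with standardization."""
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "GBM":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "NB":
        return GaussianNB(**params)
    if family == "SVM":
        clf = SVC(kernel="rbf", probability=True, random_state=seed, **params)
    elif family == "GLMnet":
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", max_iter=5000, random_state=seed, **params
        )
    elif family == "kNN":
        clf = KNeighborsClassifier(**params)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# class balancing


def balance(X: np.ndarray, y: np.ndarray, method: str, seed: int):
    """Equalize class counts in a training partition.

    down  — majority sampled without replacement to the minority size;
    over  — minority sampled with replacement to the majority size;
    smote — minority augmented with synthetic interpolants between each
            sampled minority point and one of its k=5 minority neighbours.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balancing requires exactly two classes")
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    if method == "down":
        keep = rng.choice(maj_idx, size=len(min_idx), replace=False)
        idx = np.sort(np.concatenate([min_idx, keep]))
        return X[idx], y[idx]
    if method == "over":
        extra = rng.choice(min_idx, size=len(maj_idx) - len(min_idx), replace=True)
        idx = np.sort(np.concatenate([min_idx, maj_idx, extra]))
        return X[idx], y[idx]
    if method == "smote":
        if len(min_idx) < 2:
            raise ValueError("SMOTE requires at least 2 minority samples")
        k = min(5, len(min_idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X[min_idx])
        neigh = nn.kneighbors(X[min_idx], return_distance=False)[:, 1:]
        n_new = len(maj_idx) - len(min_idx)
        base = rng.integers(0, len(min_idx), size=n_new)
        pick = rng.integers(0, k, size=n_new)
        gap = rng.uniform(0.0, 1.0, size=n_new)
        x0 = X[min_idx][base]
        x1 = X[min_idx][neigh[base, pick]]
        synth = x0 + gap[:, None] * (x1 - x0)
        Xb = np.vstack([X, synth])
        yb = np.concatenate([y, np.full(n_new, minority)])
        return Xb, yb
    raise ValueError(f"unknown balancing method {method!r}")


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricSet:
    ACC: float
    SP: float
    Recall: float
    Precision: float
    F1: float
    PR_AUC: float | None = None
    zero_denominator_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("ACC", "SP", "Recall", "Precision", "F1")}
        if self.PR_AUC is not None:
            d["PR_AUC"] = self.PR_AUC
        return d


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricSet:
    """Accuracy, specificity, recall, precision and F1 from confusion counts.

    A zero denominator yields 0 for that metric, flagged rather than raised.
    """
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    total = tp + tn + fp + fn
    if total < 1:
        raise ValueError("empty confusion table")
    flags = []

    def safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total
    sp = safe(tn, tn + fp, "SP")
    rec = safe(tp, tp + fn, "Recall")
    prec = safe(tp, tp + fp, "Precision")
    f1 = safe(2 * prec * rec, prec + rec, "F1")
    return MetricSet(acc, sp, rec, prec, f1, zero_denominator_flags=tuple(flags))


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, tn, fp, fn


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision–recall curve: the step-wise average-precision
    estimator, with tied scores handled as blocks."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("PR-AUC requires both classes")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def evaluate_scores(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> MetricSet:
    """Threshold metrics plus PR-AUC for a score vector."""
    pred = (np.asarray(scores) > threshold).astype(int)
    m = compute_metrics(*confusion_counts(labels, pred))
    auc = pr_auc(scores, labels) if len(np.unique(labels)) == 2 else None
    return MetricSet(m.ACC, m.SP, m.Recall, m.Precision, m.F1, auc, m.zero_denominator_flags)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class NestedCVResult:
    per_fold: list[MetricSet]
    chosen_params: list[dict]
    config: CVConfig
    family: str

    def mean(self) -> dict[str, float]:
        keys = self.per_fold[0].as_dict().keys()
        return {k: float(np.mean([m.as_dict()[k] for m in self.per_fold])) for k in keys}

    def std(self) -> dict[str, float]:
        keys = self.per_fold[0].as_dict().keys()
        # population SD across outer folds
        return {k: float(np.std([m.as_dict()[k] for m in self.per_fold])) for k in keys}


def _fit_scores(family, params, Xtr, ytr, Xte, balancing, seed):
    Xb, yb = balance(Xtr, ytr, balancing, seed)
    est = make_estimator(family, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence chatter on tiny folds
        est.fit(Xb, yb)
        return est, est.predict_proba(Xte)[:, 1]


def _inner_score(scores, y_true, metric):
    if metric == "PR_AUC":
        if len(np.unique(y_true)) < 2:
            return 0.0
        return pr_auc(scores, y_true)
    pred = (scores > 0.5).astype(int)
    m = compute_metrics(*confusion_counts(y_true, pred))
    return m.F1


def nested_cv(
    table,
    labels: np.ndarray,
    spec: ModelSpec,
    config: CVConfig = CVConfig(),
    feature_builder=None,
) -> NestedCVResult:
    """Nested stratified cross-validation with in-fold balancing and tuning.

    ``table`` is a FeatureTable (or gene-indexed DataFrame).  For each outer
    fold every grid point is scored on an inner stratified CV of the outer
    training set (balancing applied to the inner training partitions only);
    the winner is refit on the balanced outer training set and evaluated on
    the untouched outer test fold.  With a single-point grid the inner loop is
    skipped.

    ``feature_builder``, if given, is called as ``feature_builder(train_genes)``
    and must return a gene-indexed DataFrame of features recomputed using only
    the training genes as reference anchors — the strict no-leakage mode for
    features defined relative to the positive reference set.
    """
    if isinstance(table, pd.DataFrame):
        values = table
    elif hasattr(table, "feature_meta"):
        values = table.values
    else:
        raise TypeError("table must be a FeatureTable or a gene-indexed DataFrame")
    y = np.asarray(labels, dtype=int)
    if len(y) != len(values):
        raise ValueError("labels and feature table disagree in length")
    if len(y) < config.outer_folds:
        raise ValueError("fewer samples than outer folds")
    genes = np.asarray(values.index)
    outer = StratifiedKFold(config.outer_folds, shuffle=True, random_state=config.seed)
    grid = spec.grid_points()
    per_fold: list[MetricSet] = []
    chosen: list[dict] = []
    for k, (tr, te) in enumerate(outer.split(values, y)):
        if feature_builder is not None:
            fold_values = feature_builder(list(genes[tr]))
            fold_values = fold_values.loc[values.index]
        else:
            fold_values = values
        Xtr, ytr = fold_values.to_numpy(dtype=float)[tr], y[tr]
        Xte, yte = fold_values.to_numpy(dtype=float)[te], y[te]
        fold_seed = config.seed * 1009 + k
        if len(grid) == 1:
            best = grid[0]
        else:
            inner = StratifiedKFold(config.inner_folds, shuffle=True, random_state=fold_seed)
            best, best_score = None, -np.inf
            for params in grid:
                scores = []
                for itr, ite in inner.split(Xtr, ytr):
                    _, s = _fit_scores(
                        spec.family, params, Xtr[itr], ytr[itr], Xtr[ite],
                        config.balancing, fold_seed,
                    )
                    scores.append(_inner_score(s, ytr[ite], config.inner_metric))
                mean_score = float(np.mean(scores))
                if mean_score > best_score:
                    best, best_score = params, mean_score
        _, te_scores = _fit_scores(spec.family, best, Xtr, ytr, Xte, config.balancing, fold_seed)
        per_fold.append(evaluate_scores(te_scores, yte))
        chosen.append(dict(best))
    return NestedCVResult(per_fold, chosen, config, spec.family)


# ---------------------------------------------------------------------------
# final model


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce it."""

    estimator: object
    family: str
    selected_features: list[str]
    hyperparams: dict
    balancing: str
    seed: int
    threshold: float = 0.5

    def predict_scores(self, values: pd.DataFrame) -> pd.Series:
        """Positive-class scores in [0, 1] for a gene-indexed feature frame."""
        missing = [f for f in self.selected_features if f not in values.columns]
        if missing:
            raise KeyError(f"feature table is missing model features: {missing}")
        X = values[self.selected_features].to_numpy(dtype=float)
        return pd.Series(self.estimator.predict_proba(X)[:, 1], index=values.index, name="score")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "family": self.family,
            "selected_features": self.selected_features,
            "hyperparams": self.hyperparams,
            "balancing": self.balancing,
            "seed": self.seed,
            "threshold": self.threshold,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        joblib.dump(self.estimator, d / "model.pkl")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        est = joblib.load(d / "model.pkl")
        return cls(estimator=est, **meta)


def fit_final(
    table,
    labels: np.ndarray,
    spec: ModelSpec,
    best_hyperparams: dict,
    balancing: str = "down",
    seed: int = 0,
) -> TrainedModel:
    """Fit one model on the whole balanced training set with the chosen grid
    point (normally the winner of ``nested_cv``)."""
    values = table.values if hasattr(table, "feature_meta") else table
    y = np.asarray(labels, dtype=int)
    Xb, yb = balance(values.to_numpy(dtype=float), y, balancing, seed)
    est = make_estimator(spec.family, best_hyperparams, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xb, yb)
    return TrainedModel(
        estimator=est,
        family=spec.family,
        selected_features=list(values.columns),
        hyperparams=dict(best_hyperparams),
        balancing=balancing,
        seed=seed,
    )


def cv_report(result: NestedCVResult) -> dict:
    """JSON-serializable nested-CV report (per-fold metrics, chosen grid points)."""
    return {
        "family": result.family,
        "outer_folds": result.config.outer_folds,
        "inner_folds": result.config.inner_folds,
        "balancing": result.config.balancing,
        "seed": result.config.seed,
        "per_fold": [m.as_dict() for m in result.per_fold],
        "chosen_params": result.chosen_params,
        "mean": result.mean(),
        "std": result.std(),
    }
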