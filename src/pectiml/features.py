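"""The feature table and feature selection.

The FeatureTable is the single currency passed between pipeline stages: a
genes x features real matrix plus a category per feature (evolutionary,
expression, regulation, biochemical).  Selection proceeds in two steps, as is
usual for small-n problems with correlated descriptors:

1. redundancy filter — a greedy scan in canonical feature order drops any
   feature whose absolute Pearson correlation with an already-kept feature
   exceeds a threshold (default 0.7);
2. recursive feature elimination — iteratively fit a random forest on
   class-balanced (down-sampled) training folds, drop the least important
   feature, record cross-validated F1 per subset size, and return the subset
   with the best score (smallest on ties).

Importances are mean impurity decrease from the fitted forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

CATEGORY_ORDER = ("evolutionary", "expression", "regulation", "biochemical")


@dataclass
class FeatureTable:
    """Genes x features matrix with per-feature category metadata."""

    values: pd.DataFrame  # index: gene_id, columns: feature names
    feature_meta: dict[str, str]  # feature name -> category

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        missing = set(self.values.columns) - set(self.feature_meta)
        if missing:
            raise ValueError(f"features without a category: {sorted(missing)[:5]}")
        bad = set(self.feature_meta.values()) - set(CATEGORY_ORDER)
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def canonical_order(self) -> "FeatureTable":
        """Features sorted by category (evolutionary, expression, regulation,
        biochemical) then alphabetically — the documented tie-break order for
        the redundancy filter."""
        cols = sorted(
            self.values.columns,
            key=lambda c: (CATEGORY_ORDER.index(self.feature_meta[c]), c),
        )
        return FeatureTable(self.values[cols], dict(self.feature_meta))

    def subset(self, features: list[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureTable(self.values[list(features)], {f: self.feature_meta[f] for f in features})


def assemble_feature_table(blocks: dict[str, pd.DataFrame]) -> FeatureTable:
    """Join per-category feature blocks (category -> gene-indexed DataFrame)
    on their common gene index, in canonical order."""
    frames = []
    meta: dict[str, str] = {}
    genes = None
    for cat in CATEGORY_ORDER:
        if cat not in blocks:
            continue
        block = blocks[cat]
        genes = block.index if genes is None else genes.intersection(block.index)
        for col in block.columns:
            meta[col] = cat
        frames.append(block)
    values = pd.concat([f.loc[genes] for f in frames], axis=1)
    return FeatureTable(values, meta).canonical_order()


@dataclass
class SelectionResult:
    kept_features: list[str]
    dropped_redundant: list[tuple[str, str, float]] = field(default_factory=list)
    rfe_selected: list[str] = field(default_factory=list)
    importance: dict[str, float] = field(default_factory=dict)
    cv_scores: dict[int, float] = field(default_factory=dict)  # subset size -> CV F1


def redundancy_filter(table: FeatureTable, threshold: float = 0.7) -> SelectionResult:
    """Greedy correlation filter in input feature order.

    A feature is dropped iff its |PCC| with some already-kept feature exceeds
    the threshold; the earlier feature wins.  Constant features have undefined
    correlation, are treated as PCC 0 and kept with a warning.
    """
    names = table.feature_names
    if len(names) < 2:
        raise ValueError("need at least two features")
    X = table.values.to_numpy(dtype=float)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant feature(s) kept with correlation treated as 0: "
            f"{[n for n, c in zip(names, const) if c]}"
        )
    kept: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(names)):
        partner = None
        if not const[j]:
            for i in kept:
                if const[i]:
                    continue
                r = abs(float(np.corrcoef(X[:, i], X[:, j])[0, 1]))
                if r > threshold:
                    partner = (names[j], names[i], r)
                    break
        if partner is None:
            kept.append(j)
        else:
            dropped.append(partner)
    return SelectionResult(kept_features=[names[j] for j in kept], dropped_redundant=dropped)


def _downsample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    idx = np.concatenate(
        [rng.choice(np.flatnonzero(y == c), size=m, replace=False) for c in classes]
    )
    idx.sort()
    return X[idx], y[idx]


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def _cv_f1(X, y, cols, seed, n_folds, rf_params):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    scores = []
    for tr, te in skf.split(X, y):
        Xb, yb = _downsample(X[np.ix_(tr, cols)], y[tr], rng)
        clf = RandomForestClassifier(random_state=seed, **rf_params).fit(Xb, yb)
        scores.append(_f1(y[te], clf.predict(X[np.ix_(te, cols)])))
    return float(np.mean(scores))


def rfe_select(
    table: FeatureTable,
    labels: np.ndarray,
    seed: int = 0,
    n_folds: int = 3,
    rf_params: dict | None = None,
) -> SelectionResult:
    """Random-forest recursive feature elimination with down-sampled folds.

    Drops the single least-important feature per iteration (first minimum on
    ties), scoring each subset size by stratified cross-validated F1; the
    best-scoring subset is returned, preferring the smaller size on ties.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    rf_params = dict(rf_params or {"n_estimators": 200})
    X = table.values.to_numpy(dtype=float)
    names = table.feature_names
    cols = list(range(len(names)))
    rng = np.random.default_rng(seed)
    size_scores: dict[int, float] = {}
    subsets: dict[int, list[int]] = {}
    while cols:
        size_scores[len(cols)] = _cv_f1(X, y, cols, seed, n_folds, rf_params)
        subsets[len(cols)] = list(cols)
        if len(cols) == 1:
            break
        Xb, yb = _downsample(X[:, cols], y, rng)
        clf = RandomForestClassifier(random_state=seed, **rf_params).fit(Xb, yb)
        cols.pop(int(np.argmin(clf.feature_importances_)))
    best_size = min(size_scores, key=lambda k: (-size_scores[k], k))
    selected_cols = subsets[best_size]
    Xb, yb = _downsample(X[:, selected_cols], y, np.random.default_rng(seed))
    final = RandomForestClassifier(random_state=seed, **rf_params).fit(Xb, yb)
    importance = {
        names[c]: float(v) for c, v in zip(selected_cols, final.feature_importances_)
    }
    return SelectionResult(
        kept_features=names,
        rfe_selected=[names[c] for c in selected_cols],
        importance=importance,
        cv_scores=size_scores,
    )


def importance_ranking(model, table: FeatureTable) -> dict[str, float]:
    """Impurity importances of a fitted random forest, sorted descending."""
    rf = getattr(model, "estimator", model)
    if not isinstance(rf, RandomForestClassifier):
        raise TypeError("impurity importance ranking requires a fitted random forest")
    feats = getattr(model, "selected_features", table.feature_names)
    imp = dict(zip(feats, rf.feature_importances_))
    return dict(sorted(imp.items(), key=lambda kv: (-kv[1], kv[0])))
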