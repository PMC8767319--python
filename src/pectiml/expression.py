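"""Expression summaries and co-expression features (PCC and mutual information).

Each gene contributes four per-gene summaries of its expression profile across
conditions (min, max, mean, population variance) and four co-expression
summaries against the reference positive set: the median and maximum Pearson
correlation, and the median and minimum mutual information.  MI is estimated
with equal-frequency binning (default 5 bins) and the plug-in estimator in
natural log; the discretization is deterministic with ties broken by stable
rank order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_BINS = 5


def expression_summary(row: np.ndarray) -> tuple[float, float, float, float]:
    """(min, max, mean, population variance) of one expression profile."""
    x = np.asarray(row, dtype=float)
    if x.size == 0:
        raise ValueError("empty expression row")
    return float(x.min()), float(x.max()), float(x.mean()), float(x.var())


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation.

    A constant vector makes the correlation undefined; 0 is returned with a
    warning so degenerate (pseudo-gene-like) rows do not poison summaries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector in PCC; returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins.

    Values are ranked with a stable sort, so the assignment is deterministic;
    tied values always share the bin of their first occurrence in rank order
    (hence a constant vector occupies a single bin and has zero entropy).
    """
    x = np.asarray(x)
    n = x.size
    order = np.argsort(x, kind="stable")
    bins_sorted = np.arange(n) * bins // n
    sorted_vals = x[order]
    run_start = np.r_[True, sorted_vals[1:] != sorted_vals[:-1]]
    run_id = np.cumsum(run_start) - 1
    bins_sorted = bins_sorted[run_start][run_id]
    idx = np.empty(n, dtype=np.intp)
    idx[order] = bins_sorted
    return idx


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Plug-in mutual information (nats) from an equal-frequency joint histogram."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if x.size < bins:
        raise ValueError(f"need at least {bins} observations for {bins} bins, got {x.size}")
    bx = equal_frequency_bins(x, bins)
    by = equal_frequency_bins(y, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    return max(mi, 0.0)  # clip tiny negative round-off


def coexpression_features(
    gene: str,
    matrix: pd.DataFrame,
    reference_positives: set[str],
    bins: int = DEFAULT_BINS,
) -> tuple[float, float, float, float]:
    """(pcc_median, pcc_max, mi_median, mi_min) of one gene against every
    reference positive, excluding the self-comparison for reference genes."""
    refs = [r for r in reference_positives if r != gene]
    if not refs:
        raise ValueError("reference set empty (or contains only the query gene)")
    missing = [r for r in refs if r not in matrix.index]
    if missing:
        raise KeyError(f"reference genes absent from expression matrix: {missing[:5]}")
    row = matrix.loc[gene].to_numpy(dtype=float)
    pccs = np.array([pcc(row, matrix.loc[r].to_numpy(dtype=float)) for r in refs])
    mis = np.array([mutual_information(row, matrix.loc[r].to_numpy(dtype=float), bins) for r in refs])
    return (
        float(np.median(pccs)),
        float(pccs.max()),
        float(np.median(mis)),
        float(mis.min()),
    )


def expression_feature_table(
    matrix: pd.DataFrame,
    reference_positives: set[str],
    bins: int = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-gene expression + co-expression features for all genes in the matrix."""
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 conditions for correlation features")
    rows = {}
    with warnings.catch_warnings():
        # constant rows are legitimate in genome-wide scans; summarised, not fatal
        warnings.simplefilter("ignore")
        for gene in matrix.index:
            mn, mx, mean, var = expression_summary(matrix.loc[gene].to_numpy(dtype=float))
            pm, px_, mm, mi_min = coexpression_features(gene, matrix, reference_positives, bins)
            rows[gene] = {
                "expr_min": mn,
                "expr_max": mx,
                "expr_mean": mean,
                "expr_var": var,
                "coexpr_pcc_median": pm,
                "coexpr_pcc_max": px_,
                "coexpr_mi_median": mm,
                "coexpr_mi_min": mi_min,
            }
    return pd.DataFrame.from_dict(rows, orient="index").loc[matrix.index]
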