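"""Evolutionary features: conservation and phylogenetic co-occurrence.

Input is an orthologue presence/absence matrix (genes x species, binary, the
focal species' column all ones).  Two kinds of features derive from it:

* conservation — the fraction of the reference species in which an orthologue
  of the gene is present (1/S when the gene exists only in the focal genome,
  1 when it is present everywhere);
* co-occurrence — Jaccard similarity of a gene's presence/absence profile to
  the profile of each reference (known pectinolytic) gene, summarized by the
  median, maximum and population standard deviation.  Similar phylogenetic
  profiles are a classic proxy for functional linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def validate_orthologues(matrix: pd.DataFrame, focal: str | None = None) -> pd.DataFrame:
    """Check a presence/absence matrix: binary entries and an all-ones focal
    column (first column by default)."""
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("orthologue matrix entries must be 0/1")
    focal = focal or matrix.columns[0]
    if not (matrix[focal] == 1).all():
        raise ValueError(f"focal-species column {focal!r} must be all ones")
    return matrix


def conservation_score(presence_row: np.ndarray) -> float:
    """Fraction of species in which the gene's orthologue is present."""
    row = np.asarray(presence_row)
    if row.sum() == 0:
        raise ValueError("all-zero presence row: gene must be present in the focal species")
    return float(row.sum()) / row.size


def jaccard(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Jaccard index of two binary presence/absence profiles.

    Intersection over union of the positions set to 1; defined as 0 when both
    profiles are all-zero so the function is total.
    """
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.size} vs {b.size}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum()) / float(union)


@dataclass(frozen=True)
class CooccurrenceSummary:
    jaccard_median: float
    jaccard_max: float
    jaccard_std: float


def cooccurrence_features(
    gene: str,
    matrix: pd.DataFrame,
    reference_positives: set[str],
) -> CooccurrenceSummary:
    """Summaries of the Jaccard scores of one gene against every reference
    gene, excluding the self-comparison when the gene is itself a reference.

    With 37 references a non-reference gene yields 37 scores and a reference
    gene 36.  Returns the median, max and population standard deviation.
    """
    refs = [r for r in reference_positives if r != gene]
    if not refs:
        raise ValueError("reference set empty (or contains only the query gene)")
    missing = [r for r in refs if r not in matrix.index]
    if missing:
        raise KeyError(f"reference genes absent from orthologue matrix: {missing[:5]}")
    row = matrix.loc[gene].to_numpy()
    scores = np.array([jaccard(row, matrix.loc[r].to_numpy()) for r in refs])
    return CooccurrenceSummary(
        jaccard_median=float(np.median(scores)),
        jaccard_max=float(scores.max()),
        jaccard_std=float(scores.std()),  # population form
    )


def evolution_feature_table(matrix: pd.DataFrame, reference_positives: set[str]) -> pd.DataFrame:
    """Per-gene conservation + co-occurrence summaries for every gene in the
    matrix, as a DataFrame indexed by gene."""
    validate_orthologues(matrix)
    rows = {}
    for gene in matrix.index:
        cs = conservation_score(matrix.loc[gene].to_numpy())
        co = cooccurrence_features(gene, matrix, reference_positives)
        rows[gene] = {
            "evo_conservation": cs,
            "evo_jaccard_median": co.jaccard_median,
            "evo_jaccard_max": co.jaccard_max,
            "evo_jaccard_std": co.jaccard_std,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[matrix.index]
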