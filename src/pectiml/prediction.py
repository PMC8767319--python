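"""Genome-wide scoring of the secretome with a trained model.

Every gene in the secretome receives a pectinolytic score in [0, 1] — the
model's positive-class probability — and a confidence tier: high for scores
strictly above 0.7, low for scores in (0.5, 0.7], none otherwise.  A gene is
called a predicted pectinase iff its score is strictly above 0.5.  Known
status is annotated from the reference labels (characterized pectinase,
previously predicted pectinase, or novel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HIGH_TIER = 0.7
PREDICT_THRESHOLD = 0.5


def score_tier(score: float) -> str:
    if score > HIGH_TIER:
        return "high"
    if score > PREDICT_THRESHOLD:
        return "low"
    return "none"


def _known_status(gene: str, labels: pd.DataFrame | None) -> str:
    if labels is None:
        return "novel"
    row = labels.loc[labels["gene_id"] == gene]
    if len(row) and row.iloc[0]["label"] == "positive":
        if row.iloc[0]["category"] == "characterized_pectinase":
            return "characterized"
        return "previously_predicted"
    return "novel"


def predict_genome(
    model,
    table,
    secretome: set[str],
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every secretome gene; deterministic given the model artifact.

    Returns a DataFrame with columns gene_id, score, predicted_label, tier,
    known_status, sorted by score descending (gene_id breaks ties so re-runs
    are byte-identical).
    """
    values = table.values if hasattr(table, "feature_meta") else table
    genes = [g for g in values.index if g in secretome]
    missing = secretome - set(values.index)
    if missing:
        raise KeyError(f"secretome genes missing from the feature table: {sorted(missing)[:5]}")
    scores = model.predict_scores(values.loc[genes])
    status = {g: _known_status(g, labels) for g in genes} if labels is not None else {}
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "score": scores.to_numpy(),
            "predicted_label": scores.to_numpy() > PREDICT_THRESHOLD,
            "tier": [score_tier(s) for s in scores],
            "known_status": [status.get(g, "novel") for g in genes],
        }
    )
    return out.sort_values(["score", "gene_id"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def evaluate_recall_of_known(records: pd.DataFrame, labels: pd.DataFrame | None = None) -> dict:
    """Count predicted (score > 0.5) genes by known status and tier.

    Returns counts of characterized / previously-predicted / novel genes among
    the predictions, tier totals, and recall fractions relative to the label
    table when provided.
    """
    if len(records) == 0:
        return {
            "n_predicted": 0, "n_high": 0, "n_low": 0,
            "characterized_predicted": 0, "previously_predicted_predicted": 0,
            "novel_predicted": 0,
        }
    hit = records[records["predicted_label"]]
    out = {
        "n_predicted": int(len(hit)),
        "n_high": int((records["tier"] == "high").sum()),
        "n_low": int((records["tier"] == "low").sum()),
        "characterized_predicted": int((hit["known_status"] == "characterized").sum()),
        "previously_predicted_predicted": int(
            (hit["known_status"] == "previously_predicted").sum()
        ),
        "novel_predicted": int((hit["known_status"] == "novel").sum()),
    }
    if labels is not None:
        pos = labels[labels["label"] == "positive"]
        n_char = int((pos["category"] == "characterized_pectinase").sum())
        n_pred = int((pos["category"] == "predicted_pectinase").sum())
        scored = set(records["gene_id"])
        if n_char:
            out["characterized_recall"] = out["characterized_predicted"] / n_char
        if n_pred:
            out["previously_predicted_recall"] = out["previously_predicted_predicted"] / n_pred
        out["n_reference_positives_scored"] = int(len(scored & set(pos["gene_id"])))
    return out
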