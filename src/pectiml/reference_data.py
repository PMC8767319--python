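"""Reference gene sets, the train/test split and the secretome filter.

The prediction problem is framed against a curated benchmark: a small positive
class of experimentally characterized extracellular pectinolytic enzymes and a
several-fold larger negative class of secreted, non-pectinolytic proteins
(non-pectin CAZymes, peptidases, transporters, cytochrome P450s, ...).
Negatives are split 3:1 into a training and an independent test partition;
positives for the independent test come from an earlier homology/transcriptome
study, minus genes already used for training and minus unexpressed pseudo
genes.  Genome-wide scoring is restricted to the secretome, defined as the
union of a SignalP hmm-score cut and a Phobius secretion call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LABELS = ("positive", "negative")
CATEGORIES = (
    "characterized_pectinase",
    "predicted_pectinase",
    "non_pectin_cazy",
    "peptidase",
    "transporter",
    "non_pbd_cazy",
    "cytochrome_p450",
)
PARTITIONS = ("train", "test", "unassigned")


@dataclass(frozen=True)
class DataSplit:
    """A seeded partition of a gene list into train and test sets."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: tuple[int, int]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def validate_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Validate a reference label table (gene_id, label, category, partition).

    Positives in the training partition must be characterized pectinases;
    positives in the test partition must be previously predicted pectinases.
    """
    required = {"gene_id", "label", "category", "partition"}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    if labels["gene_id"].duplicated().any():
        dups = labels.loc[labels["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_ids in label table: {dups[:5]}")
    for col, allowed in (
        ("label", LABELS),
        ("category", CATEGORIES),
        ("partition", PARTITIONS),
    ):
        bad = set(labels[col]) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    pos = labels[labels["label"] == "positive"]
    bad_train = pos[(pos["partition"] == "train") & (pos["category"] != "characterized_pectinase")]
    if len(bad_train):
        raise ValueError("positive training genes must have category characterized_pectinase")
    bad_test = pos[(pos["partition"] == "test") & (pos["category"] != "predicted_pectinase")]
    if len(bad_test):
        raise ValueError("positive test genes must have category predicted_pectinase")
    return labels


def split_negatives(negatives: list[str], ratio: tuple[int, int] = (3, 1), seed: int = 0) -> DataSplit:
    """Randomly split a negative gene list into train/test at the given ratio.

    The training share is rounded half-up, so 310 genes at 3:1 give 233 train
    and 77 test.  Assignment is a seeded uniform permutation and is
    deterministic for a fixed seed.
    """
    if len(negatives) == 0:
        raise ValueError("cannot split an empty gene list")
    r1, r2 = ratio
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"ratio components must be positive, got {ratio}")
    n = len(negatives)
    # round-half-up of n*r1/(r1+r2) in exact integer arithmetic
    n_train = (2 * n * r1 + (r1 + r2)) // (2 * (r1 + r2))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    arr = np.asarray(negatives, dtype=object)
    train = tuple(arr[perm[:n_train]])
    test = tuple(arr[perm[n_train:]])
    return DataSplit(train_ids=train, test_ids=test, ratio=(r1, r2), seed=seed)


def secretome_filter(
    annotations: pd.DataFrame,
    signalp_threshold: float = 0.8,
    genes: list[str] | None = None,
) -> set[str]:
    """Return the secretome: genes with SignalP hmm-score strictly above the
    threshold OR a positive Phobius call (union rule).

    ``annotations`` needs columns gene_id, signalp_hmm_score, phobius_secreted.
    If ``genes`` is given, only those genes are considered; queried genes with
    no annotation are excluded with a warning (conservative).
    """
    ann = annotations.set_index("gene_id")
    scores = ann["signalp_hmm_score"].astype(float)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("signalp_hmm_score values must lie in [0, 1]")
    secreted = (scores > signalp_threshold) | ann["phobius_secreted"].astype(bool)
    result = set(secreted.index[secreted])
    if genes is not None:
        missing = [g for g in genes if g not in ann.index]
        if missing:
            warnings.warn(
                f"{len(missing)} queried gene(s) lack secretion annotation and are "
                f"excluded from the secretome (e.g. {missing[:3]})"
            )
        result &= set(genes)
    return result


def assemble_test_positives(
    candidate_list: list[str],
    train_positives: set[str],
    expressed: set[str],
) -> list[str]:
    """Build the independent-test positive set from a prior candidate list.

    Removes candidates already used as training positives and candidates with
    no detectable expression (pseudo genes).  Order-stable: e.g. 60 candidates
    minus 37 training genes minus 14 unexpressed leave 9.
    """
    return [g for g in candidate_list if g not in train_positives and g in expressed]


def expressed_genes(expression: pd.DataFrame, floor: float = 0.0) -> set[str]:
    """Genes whose maximum expression over all conditions strictly exceeds
    ``floor`` (the matrix's detection floor, default 0)."""
    return set(expression.index[expression.max(axis=1) > floor])
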