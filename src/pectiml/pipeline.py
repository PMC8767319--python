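"""End-to-end glue: load a data directory, build the feature table, train,
and score the secretome.

Feature channels defined *relative to the positive reference set* (Jaccard
co-occurrence, co-expression PCC/MI) anchor, by default, on the characterized
positives of the training partition.  For strict leakage-free cross-validation
``fold_feature_builder`` recomputes those channels per fold using only the
fold's training positives as references.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import biochem, evolutionary, expression, io, regulation
from .features import FeatureTable, assemble_feature_table
from .synthetic import SyntheticDataset


@dataclass
class Dataset:
    """In-memory bundle of all pipeline inputs."""

    orthologues: pd.DataFrame
    expression: pd.DataFrame
    regulation: pd.DataFrame
    promoters: dict[str, str] | None
    motifs: pd.DataFrame | None
    proteins: pd.DataFrame
    secretion: pd.DataFrame
    labels: pd.DataFrame

    @classmethod
    def from_dir(cls, directory: str | Path) -> "Dataset":
        d = Path(directory)
        promoters = None
        motifs = None
        if (d / "promoters.fasta").exists():
            promoters = io.read_promoters(d / "promoters.fasta")
        if (d / "motifs.tsv").exists():
            motifs = io.read_motifs(d / "motifs.tsv")
        return cls(
            orthologues=io.read_orthologues(d / "orthologues.tsv"),
            expression=io.read_expression(d / "expression.tsv"),
            regulation=io.read_regulation(d / "regulation.tsv"),
            promoters=promoters,
            motifs=motifs,
            proteins=io.read_proteins(d / "proteins.tsv"),
            secretion=io.read_secretion(d / "secretion.tsv"),
            labels=io.read_labels(d / "labels.tsv"),
        )

    @classmethod
    def from_synthetic(cls, ds: SyntheticDataset) -> "Dataset":
        return cls(
            orthologues=ds.orthologues,
            expression=ds.expression,
            regulation=ds.regulation,
            promoters=ds.promoters,
            motifs=ds.motifs,
            proteins=ds.proteins,
            secretion=ds.secretion,
            labels=ds.labels,
        )

    def reference_positives(self) -> set[str]:
        """Characterized pectinases of the training partition — the default
        anchor set for co-occurrence and co-expression features."""
        lab = self.labels
        return set(
            lab.loc[
                (lab["label"] == "positive") & (lab["partition"] == "train"), "gene_id"
            ]
        )

    def training_frame(self, table: FeatureTable):
        """(features, binary labels) restricted to the training partition."""
        lab = self.labels.set_index("gene_id")
        genes = [g for g in table.genes if lab.loc[g, "partition"] == "train"]
        y = np.array([1 if lab.loc[g, "label"] == "positive" else 0 for g in genes])
        return table.subset(table.feature_names).values.loc[genes], y


def build_feature_table(
    dataset: Dataset,
    reference_positives: set[str] | None = None,
    bins: int = 5,
) -> FeatureTable:
    """Assemble all four feature categories into one gene-indexed table."""
    refs = reference_positives if reference_positives is not None else dataset.reference_positives()
    if not refs:
        raise ValueError("no reference positives to anchor co-occurrence/co-expression features")
    blocks = {
        "evolutionary": evolutionary.evolution_feature_table(dataset.orthologues, refs),
        "expression": expression.expression_feature_table(dataset.expression, refs, bins=bins),
        "regulation": regulation.regulation_feature_table(
            dataset.regulation, dataset.promoters, dataset.motifs
        ),
        "biochemical": biochem.biochemical_feature_table(dataset.proteins),
    }
    return assemble_feature_table(blocks)


def fold_feature_builder(dataset: Dataset, bins: int = 5):
    """A ``feature_builder`` for strict nested CV: given the training genes of
    a fold, recompute reference-anchored features using only the positive
    labels inside that training partition."""
    lab = dataset.labels.set_index("gene_id")

    def build(train_genes: list[str]) -> pd.DataFrame:
        refs = {g for g in train_genes if lab.loc[g, "label"] == "positive"}
        table = build_feature_table(dataset, reference_positives=refs, bins=bins)
        return table.values

    return build
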