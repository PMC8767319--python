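"""Readers and writers for the tab-separated interchange files.

All tables are UTF-8 TSV with a header row; promoters and genomes are FASTA.
Loaders validate the invariants each stage relies on (binary orthologue
entries, ternary regulation calls, NA-free expression unless imputation is
requested) so downstream code can assume well-formed inputs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import evolutionary, regulation as _regulation
from .reference_data import validate_labels


def read_labels(path: str | Path) -> pd.DataFrame:
    return validate_labels(pd.read_csv(path, sep="\t", dtype=str))


def read_secretion(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["signalp_hmm_score"] = df["signalp_hmm_score"].astype(float)
    df["phobius_secreted"] = df["phobius_secreted"].astype(int).astype(bool)
    return df


def read_orthologues(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return evolutionary.validate_orthologues(df.astype(int))


def read_expression(path: str | Path, impute: str | None = None) -> pd.DataFrame:
    """Load an expression matrix (gene_id + one column per condition).

    Missing entries are rejected unless ``impute='min'``, which fills each
    gene's missing conditions with that gene's row minimum.
    """
    df = pd.read_csv(path, sep="\t", index_col="gene_id").astype(float)
    if df.isna().any().any():
        if impute == "min":
            warnings.warn("imputing missing expression values with row minima")
            df = df.apply(lambda row: row.fillna(row.min()), axis=1)
            if df.isna().any().any():
                raise ValueError("rows with no observed values cannot be imputed")
        else:
            raise ValueError("expression matrix contains NA (pass impute='min' to fill)")
    return df


def read_regulation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id").astype(int)
    return _regulation.validate_ternary(df)


def read_de_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    """One TSV per TF-mutant comparison (gene_id, log2FC, padj); the file stem
    names the comparison."""
    out = {}
    for p in sorted(Path(directory).glob("*.tsv")):
        out[p.stem] = pd.read_csv(p, sep="\t")
    if not out:
        raise FileNotFoundError(f"no .tsv differential-expression tables in {directory}")
    return out


def read_motifs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tf", "iupac_motif"} <= set(df.columns):
        raise ValueError("motifs table needs columns tf, iupac_motif")
    for m in df["iupac_motif"]:
        if len(m) < 4:
            raise ValueError(f"motif {m!r} shorter than 4 nt")
        _regulation._motif_regex(m)  # raises on invalid IUPAC codes
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_promoters(path: str | Path, max_length: int = 1000) -> dict[str, str]:
    seqs = read_fasta(path)
    for gene, seq in seqs.items():
        if len(seq) > max_length:
            raise ValueError(f"promoter of {gene} longer than {max_length} bp")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter of {gene} has invalid characters {sorted(bad)}")
    return seqs


def read_proteins(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "length", "n_pfam"}
    if not needed <= set(df.columns):
        raise ValueError(f"protein table needs columns {sorted(needed)} (+ optional pI)")
    return df


def write_features(table, path: str | Path, meta_path: str | Path | None = None) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id")
    if meta_path is not None:
        pd.DataFrame(
            {"feature": list(table.feature_meta), "category": list(table.feature_meta.values())}
        ).to_csv(meta_path, sep="\t", index=False)


def read_features(path: str | Path, meta_path: str | Path):
    from .features import FeatureTable

    values = pd.read_csv(path, sep="\t", index_col="gene_id").astype(float)
    meta = pd.read_csv(meta_path, sep="\t")
    return FeatureTable(values, dict(zip(meta["feature"], meta["category"])))


def write_predictions(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    out["predicted_label"] = out["predicted_label"].astype(int)
    out["score"] = out["score"].map(lambda s: f"{s:.6f}")
    out.to_csv(path, sep="\t", index=False)
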