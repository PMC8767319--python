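"""Transcription-factor regulation features.

Two feature channels:

* ternary regulation calls — each gene is +1 / -1 / 0 in each TF-mutant vs
  reference-strain comparison (up-regulated, down-regulated, unchanged),
  derived from log2 fold changes and adjusted p-values, or supplied directly
  as a precomputed ternary table;
* promoter binding-site counts — the number of matches of each TF's
  IUPAC-degenerate binding motif (and its reverse complement) in the 1000 bp
  region upstream of the translation start.
"""

from __future__ import annotations

import re
import warnings

import pandas as pd
from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_PROMOTER_LENGTH = 1000


def encode_regulation(
    de_tables: dict[str, pd.DataFrame],
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Ternary regulation table from per-comparison differential-expression tables.

    Each table needs columns gene_id, log2FC, padj.  A gene is +1 when
    log2FC >= fc_threshold with padj < p_threshold, -1 when
    log2FC <= -fc_threshold with padj < p_threshold, else 0.  Genes missing
    from a comparison get 0 with a warning.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive (log2 scale)")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    if genes is None:
        genes = sorted(set().union(*(set(t["gene_id"]) for t in de_tables.values())))
    out = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=list(de_tables), dtype=int)
    for comp, table in de_tables.items():
        t = table.set_index("gene_id")
        missing = [g for g in genes if g not in t.index]
        if missing:
            warnings.warn(
                f"{len(missing)} gene(s) missing from comparison {comp!r}; call set to 0"
            )
        present = [g for g in genes if g in t.index]
        fc = t.loc[present, "log2FC"].astype(float)
        p = t.loc[present, "padj"].astype(float)
        call = pd.Series(0, index=fc.index, dtype=int)
        call[(fc >= fc_threshold) & (p < p_threshold)] = 1
        call[(fc <= -fc_threshold) & (p < p_threshold)] = -1
        out.loc[present, comp] = call
    return out


def validate_ternary(table: pd.DataFrame) -> pd.DataFrame:
    """Check a precomputed ternary regulation table (entries in {-1, 0, 1})."""
    bad = ~table.isin((-1, 0, 1))
    if bad.any().any():
        raise ValueError("regulation calls must be -1, 0 or +1")
    return table


def extract_promoter(
    genome: dict[str, str],
    contig: str,
    start: int,
    end: int,
    strand: str,
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> str:
    """Up to ``length`` bases immediately 5' of the translation start.

    Coordinates are 1-based closed (GFF convention); minus-strand promoters
    are reverse-complemented so the returned string reads 5'->3' relative to
    the gene.  Truncated at the contig boundary, with a warning when short.
    """
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not in genome")
    seq = genome[contig]
    if strand == "+":
        hi = start - 1  # 0-based index of the translation start
        lo = max(0, hi - length)
        promoter = seq[lo:hi]
    elif strand == "-":
        lo = end  # first base past the gene in genome coordinates
        hi = min(len(seq), lo + length)
        promoter = str(Seq(seq[lo:hi]).reverse_complement())
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if len(promoter) < length:
        warnings.warn(
            f"promoter truncated to {len(promoter)} bp at contig boundary "
            f"({contig}:{start}-{end}{strand})"
        )
    return promoter


def _motif_regex(motif: str) -> re.Pattern:
    bad = [c for c in motif.upper() if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) in motif {motif!r}: {bad}")
    # lookahead so overlapping matches are all counted; classes contain only
    # ACGT, so an N in the *sequence* never matches
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in motif.upper()) + ")")


def motif_count(promoter: str, motif: str) -> int:
    """Occurrences of an IUPAC motif in a promoter, counting overlaps, on the
    given strand plus occurrences of its reverse complement on the same strand.

    Palindromic motifs therefore count twice per site — deterministic and
    documented.  N in the sequence never matches.
    """
    pat = _motif_regex(motif)
    seq = promoter.upper()
    n = len(pat.findall(seq))
    rc = str(Seq(motif.upper()).reverse_complement())
    n += len(_motif_regex(rc).findall(seq))
    return n


def regulation_feature_table(
    ternary: pd.DataFrame,
    promoters: dict[str, str] | None = None,
    motifs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble regulation features: one ternary column per TF comparison
    (``reg_<tf>``) plus one motif-count column per TF with a known motif
    (``motif_<tf>``).  ``motifs`` needs columns tf, iupac_motif."""
    validate_ternary(ternary)
    out = ternary.add_prefix("reg_").astype(float)
    if motifs is not None and promoters is not None:
        for _, row in motifs.iterrows():
            tf, motif = row["tf"], row["iupac_motif"]
            counts = {g: float(motif_count(promoters.get(g, ""), motif)) for g in ternary.index}
            out[f"motif_{tf}"] = pd.Series(counts)
    return out
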