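"""Biochemical features: protein length, isoelectric point and Pfam-domain count.

Properties are normally consumed from a precomputed table.  When the pI
column is blank and the protein sequence is available, the isoelectric point
is computed from the sequence: the pH at which the Henderson–Hasselbalch net
charge is zero, located by bisection.  The pKa set is the EMBOSS convention:

    N-terminus 8.6, C-terminus 3.6,
    C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

# EMBOSS pKa values
PKA_POSITIVE = {"NTERM": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"CTERM": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    pI: float | None
    n_pfam: int
    incomplete: bool = False


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH.

    Strictly decreasing in pH, which guarantees bisection convergence.
    """
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["NTERM"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["CTERM"] - ph))
    for aa in sequence:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def compute_pi(sequence: str, tol: float = 1e-3) -> float:
    """Isoelectric point: the pH in [0, 14] where the net charge vanishes,
    found by bisection to ``tol``.  Non-standard letters are ignored with a
    warning; an empty sequence is an error."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    unknown = sorted(set(seq) - AMINO_ACIDS)
    if unknown:
        warnings.warn(f"ignoring non-standard residue(s) {unknown} in pI computation")
        seq = "".join(c for c in seq if c in AMINO_ACIDS)
        if not seq:
            raise ValueError("sequence contains no standard amino acids")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def load_properties(
    table: pd.DataFrame,
    sequences: dict[str, str] | None = None,
) -> dict[str, ProteinProperties]:
    """Per-gene properties from a table with columns gene_id, length, pI, n_pfam.

    Blank pI falls back to ``compute_pi`` on the sequence when available,
    otherwise the record is flagged incomplete.  Non-numeric fields raise with
    the offending row number.
    """
    sequences = sequences or {}
    out: dict[str, ProteinProperties] = {}
    for i, row in enumerate(table.itertuples(index=False)):
        gene = row.gene_id
        try:
            length = int(row.length)
            n_pfam = int(row.n_pfam)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric length/n_pfam in row {i} (gene {gene!r})") from exc
        if length < 1:
            raise ValueError(f"protein length must be >= 1 in row {i} (gene {gene!r})")
        raw_pi = getattr(row, "pI", None)
        if raw_pi is None or (isinstance(raw_pi, float) and pd.isna(raw_pi)) or raw_pi == "":
            if gene in sequences:
                out[gene] = ProteinProperties(length, compute_pi(sequences[gene]), n_pfam)
            else:
                out[gene] = ProteinProperties(length, None, n_pfam, incomplete=True)
        else:
            try:
                pi = float(raw_pi)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-numeric pI in row {i} (gene {gene!r})") from exc
            out[gene] = ProteinProperties(length, pi, n_pfam)
    return out


def biochemical_feature_table(
    table: pd.DataFrame,
    sequences: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Protein length / pI / Pfam-count features as a gene-indexed DataFrame.
    Incomplete records (no pI and no sequence) are rejected."""
    props = load_properties(table, sequences)
    incomplete = [g for g, p in props.items() if p.incomplete]
    if incomplete:
        raise ValueError(f"genes with no pI and no sequence: {incomplete[:5]}")
    return pd.DataFrame(
        {
            "prot_length": {g: float(p.length) for g, p in props.items()},
            "prot_pi": {g: float(p.pI) for g, p in props.items()},
            "prot_n_pfam": {g: float(p.n_pfam) for g, p in props.items()},
        }
    ).loc[table["gene_id"]]
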