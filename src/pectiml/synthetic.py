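"""Synthetic multi-omics benchmark generator with planted positive structure.

The generator emits the full input set the pipeline consumes — orthologue
presence/absence matrix, expression matrix, ternary TF-regulation table,
promoters + TF motifs, protein property table, secretion annotations and
reference labels — with a planted positive class whose signal lives in the
channels the prediction problem cares about:

* a shared latent expression factor (pairwise co-expression among positives);
* phylogenetic profiles perturbed from a common template (high Jaccard);
* concordant calls under "pectin TF" mutant comparisons (activator deletions
  down-regulate positives, repressor deletions up-regulate them);
* promoter enrichment of the pectin-TF binding motifs;
* a shifted isoelectric-point distribution.

Every knob has a null setting (coexpr_strength 0, profile_similarity 0.5,
regulation_concordance 0.5, motif_enrichment 1, pi_shift 0) at which
positives are statistically indistinguishable from the background, so
permutation and null-configuration tests have an exact reference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_data import split_negatives

TF_NAMES = ("gaaR", "araR", "rhaR", "xlnR", "amyR", "creA", "gaaX")
# deletion of an activator drives targets down; of a repressor, up
PECTIN_ACTIVATORS = ("gaaR", "araR", "rhaR")
PECTIN_REPRESSORS = ("gaaX",)
TF_MOTIFS = {"gaaR": "CCNCCAAT", "araR": "CGGDTAAW", "creA": "SYGGRG"}

NEGATIVE_CATEGORIES = ("non_pectin_cazy", "peptidase", "transporter", "non_pbd_cazy", "cytochrome_p450")
# proportions mirror the five published negative category sizes
NEGATIVE_WEIGHTS = (34, 53, 81, 88, 59)


@dataclass(frozen=True)
class SyntheticConfig:
    n_pos: int = 40
    n_neg: int = 300
    n_species: int = 10
    n_conditions: int = 40
    n_tf_comparisons: int = 7
    coexpr_strength: float = 0.7
    profile_similarity: float = 0.8
    regulation_concordance: float = 0.8
    motif_enrichment: float = 4.0
    pi_shift: float = -1.0
    noise_sd: float = 1.0
    seed: int = 0
    promoter_length: int = 1000
    characterized_fraction: float = 0.8  # share of positives used as training references
    background_motif_rate: float = 0.4  # planted copies per promoter per motif
    pectin_condition_fraction: float = 0.25

    def __post_init__(self):
        for name in ("coexpr_strength", "profile_similarity", "regulation_concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.motif_enrichment < 1.0:
            raise ValueError("motif_enrichment must be >= 1")
        for name in ("n_pos", "n_neg", "n_species", "n_conditions", "n_tf_comparisons"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    orthologues: pd.DataFrame
    expression: pd.DataFrame
    regulation: pd.DataFrame
    promoters: dict[str, str]
    motifs: pd.DataFrame
    proteins: pd.DataFrame
    secretion: pd.DataFrame
    labels: pd.DataFrame
    truth: pd.DataFrame = field(default=None)

    def write(self, outdir: str | Path) -> None:
        """Write the full TSV/FASTA input set plus truth.tsv."""
        d = Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        self.orthologues.to_csv(d / "orthologues.tsv", sep="\t", index_label="gene_id")
        self.expression.to_csv(d / "expression.tsv", sep="\t", index_label="gene_id")
        self.regulation.to_csv(d / "regulation.tsv", sep="\t", index_label="gene_id")
        self.motifs.to_csv(d / "motifs.tsv", sep="\t", index=False)
        self.proteins.to_csv(d / "proteins.tsv", sep="\t", index=False)
        self.secretion.to_csv(d / "secretion.tsv", sep="\t", index=False)
        self.labels.to_csv(d / "labels.tsv", sep="\t", index=False)
        self.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
        with open(d / "promoters.fasta", "w") as fh:
            for gene, seq in self.promoters.items():
                fh.write(f">{gene}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def _tf_names(n: int) -> list[str]:
    names = list(TF_NAMES[:n])
    names += [f"tf{i}" for i in range(len(names) + 1, n + 1)]
    return names


def _plant_motif(seq: np.ndarray, motif: str, pos: int, rng: np.random.Generator) -> None:
    from .regulation import IUPAC

    for j, code in enumerate(motif):
        seq[pos + j] = rng.choice(list(IUPAC[code]))


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate the complete synthetic input set; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n_pos, n_neg = config.n_pos, config.n_neg
    n = n_pos + n_neg
    pos_genes = [f"pg{i:04d}" for i in range(1, n_pos + 1)]
    neg_genes = [f"ng{i:04d}" for i in range(1, n_neg + 1)]
    genes = pos_genes + neg_genes
    is_pos = np.array([True] * n_pos + [False] * n_neg)

    # --- orthologue presence/absence ------------------------------------
    species = [f"sp{j:02d}" for j in range(1, config.n_species + 1)]  # sp01 = focal
    template = (rng.random(config.n_species) < 0.7).astype(int)
    template[0] = 1
    # positives match the template per species with probability
    # profile_similarity, realized as a template/Bernoulli(0.5) mixture with
    # weight m = 2s-1 so that s = 0.5 degenerates to the background law
    m = max(0.0, 2.0 * config.profile_similarity - 1.0)
    presence = np.zeros((n, config.n_species), dtype=int)
    for i in range(n):
        background = (rng.random(config.n_species) < 0.5).astype(int)
        if is_pos[i]:
            keep = rng.random(config.n_species) < m
            row = np.where(keep, template, background)
        else:
            row = background
        row[0] = 1
        presence[i] = row
    orthologues = pd.DataFrame(presence, index=genes, columns=species)

    # --- expression ------------------------------------------------------
    conds = [f"pectin{j:02d}" for j in range(1, int(config.n_conditions * config.pectin_condition_fraction) + 1)]
    conds += [f"carbon{j:02d}" for j in range(1, config.n_conditions - len(conds) + 1)]
    rho = min(config.coexpr_strength, 0.99)
    loading = config.noise_sd * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    factor = rng.normal(0.0, 1.0, config.n_conditions)
    baseline = rng.normal(5.0, 1.5, n)
    noise = rng.normal(0.0, config.noise_sd, (n, config.n_conditions))
    expr = baseline[:, None] + noise
    pectin_block = np.array([c.startswith("pectin") for c in conds], dtype=float)
    expr[is_pos] += loading * factor[None, :]
    expr[is_pos] += 2.0 * config.coexpr_strength * pectin_block[None, :]
    expression = pd.DataFrame(expr, index=genes, columns=conds)

    # --- regulation -------------------------------------------------------
    tfs = _tf_names(config.n_tf_comparisons)
    reg = np.zeros((n, len(tfs)), dtype=int)
    for j, tf in enumerate(tfs):
        pectin_tf = tf in PECTIN_ACTIVATORS or tf in PECTIN_REPRESSORS
        p_resp = 0.6 if pectin_tf else 0.3
        concordant_sign = -1 if tf in PECTIN_ACTIVATORS else 1
        responsive = rng.random(n) < p_resp
        signs = np.where(rng.random(n) < 0.5, 1, -1)
        if pectin_tf:
            concord = rng.random(n) < config.regulation_concordance
            signs_pos = np.where(concord, concordant_sign, -concordant_sign)
            signs = np.where(is_pos, signs_pos, signs)
        reg[:, j] = np.where(responsive, signs, 0)
    regulation = pd.DataFrame(reg, index=genes, columns=tfs)

    # --- promoters + motifs ----------------------------------------------
    motifs = pd.DataFrame(
        [(tf, m) for tf, m in TF_MOTIFS.items() if tf in tfs],
        columns=["tf", "iupac_motif"],
    )
    pectin_motif_tfs = {tf for tf in TF_MOTIFS if tf in PECTIN_ACTIVATORS or tf in PECTIN_REPRESSORS}
    promoters: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for i, gene in enumerate(genes):
        seq = bases[rng.integers(0, 4, config.promoter_length)]
        for _, row in motifs.iterrows():
            rate = config.background_motif_rate
            if is_pos[i] and row["tf"] in pectin_motif_tfs:
                rate *= config.motif_enrichment
            for _ in range(rng.poisson(rate)):
                pos = int(rng.integers(0, config.promoter_length - len(row["iupac_motif"])))
                _plant_motif(seq, row["iupac_motif"], pos, rng)
        promoters[gene] = "".join(seq)

    # --- proteins ---------------------------------------------------------
    length = np.round(np.exp(rng.normal(6.0, 0.4, n))).astype(int).clip(min=50)
    pi = rng.normal(6.0, 1.3, n)
    pi[is_pos] += config.pi_shift
    pi = pi.clip(3.0, 12.0)
    n_pfam = rng.poisson(1.2, n)
    proteins = pd.DataFrame(
        {"gene_id": genes, "length": length, "pI": np.round(pi, 3), "n_pfam": n_pfam}
    )

    # --- secretion: every synthetic gene is in the prediction universe ----
    secretion = pd.DataFrame(
        {
            "gene_id": genes,
            "signalp_hmm_score": np.round(rng.uniform(0.0, 1.0, n), 4),
            "phobius_secreted": np.ones(n, dtype=int),
        }
    )

    # --- labels -----------------------------------------------------------
    n_char = max(1, round(config.characterized_fraction * n_pos))
    pos_cat = ["characterized_pectinase"] * n_char + ["predicted_pectinase"] * (n_pos - n_char)
    pos_part = ["train"] * n_char + ["test"] * (n_pos - n_char)
    w = np.array(NEGATIVE_WEIGHTS, dtype=float)
    sizes = np.floor(w / w.sum() * n_neg).astype(int)
    sizes[0] += n_neg - sizes.sum()
    neg_cat = [c for c, s in zip(NEGATIVE_CATEGORIES, sizes) for _ in range(s)]
    split = split_negatives(neg_genes, (3, 1), seed=config.seed)
    train_neg = set(split.train_ids)
    neg_part = ["train" if g in train_neg else "test" for g in neg_genes]
    labels = pd.DataFrame(
        {
            "gene_id": genes,
            "label": ["positive"] * n_pos + ["negative"] * n_neg,
            "category": pos_cat + neg_cat,
            "partition": pos_part + neg_part,
        }
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "truth": ["planted_positive" if p else "background" for p in is_pos]}
    )
    return SyntheticDataset(
        config=config,
        orthologues=orthologues,
        expression=expression,
        regulation=regulation,
        promoters=promoters,
        motifs=motifs,
        proteins=proteins,
        secretion=secretion,
        labels=labels,
        truth=truth,
    )


def truth_table(dataset: SyntheticDataset) -> dict[str, str]:
    """Ground-truth map gene -> {planted_positive, background}."""
    return dict(zip(dataset.truth["gene_id"], dataset.truth["truth"]))


def make_planted_features(
    n_pos: int = 40,
    n_neg: int = 80,
    n_informative: int = 5,
    n_noise: int = 20,
    effect: float = 1.5,
    seed: int = 0,
):
    """A plain planted-feature design for selection benchmarks: informative
    features are mean-shifted by ``effect`` for positives, noise features are
    pure N(0,1).  Returns (FeatureTable, labels, informative feature names)."""
    from .features import FeatureTable

    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    X = rng.normal(0.0, 1.0, (n, n_informative + n_noise))
    X[y == 1, :n_informative] += effect
    names = [f"inf{i:02d}" for i in range(n_informative)] + [f"noise{i:02d}" for i in range(n_noise)]
    genes = [f"g{i:04d}" for i in range(n)]
    values = pd.DataFrame(X, index=genes, columns=names)
    meta = {c: "expression" for c in names}
    return FeatureTable(values, meta), y, names[:n_informative]
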