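# Methods

## Problem setting

`pectiml` treats pectinolytic-enzyme discovery in *Aspergillus niger* as
binary classification over the secretome with a rare positive class. The
benchmark structure it assumes: a few dozen experimentally characterized
extracellular pectinases as training positives; a several-fold larger
negative set of secreted but non-pectinolytic proteins drawn from five
functional groups (non-pectin plant-biomass CAZymes, peptidases,
transporters, other CAZymes, cytochrome P450s); negatives split 3:1 into
training and independent-test partitions; and a positive test set of
previously predicted (not yet characterized) pectinases that excludes the
training genes and unexpressed pseudo genes. The prediction universe is the
secretome, defined by the union rule: SignalP hmm-score strictly above 0.8
*or* a positive Phobius call. Genes lacking secretion annotation are excluded
conservatively, with a warning.

The 3:1 split rounds the training share half-up (310 negatives give
233 train / 77 test), with a seeded uniform permutation deciding membership.

## Features

All reference-anchored features compare a gene against the *characterized
positives of the training partition*; when the gene is itself a reference the
self-comparison is excluded, so a reference gene is summarized over one fewer
score than a non-reference gene.

**Evolutionary.** Conservation is the fraction of reference species carrying
an orthologue (the focal species always does, so the score lies in
[1/S, 1]). Co-occurrence is the Jaccard index of binary presence/absence
profiles; per gene we keep the median, maximum and population standard
deviation of its scores against the references. Jaccard of two all-zero
profiles is defined as 0 so the function is total on synthetic inputs.

**Expression.** Per-gene min / max / mean / population variance across
conditions, plus co-expression with the references: median and maximum
Pearson correlation, median and minimum mutual information. A constant
profile makes PCC undefined; we return 0 with a warning so pseudo-gene-like
rows do not poison the summaries. MI uses equal-frequency binning (default
5 bins) and the plug-in estimator in natural log. The discretization is
deterministic: values are ranked with a stable sort and tied values always
share the bin of their first occurrence in rank order — hence a constant
vector occupies one bin (zero entropy, MI 0) and MI(x, x) = log(bins) when
the sample size divides evenly. The bin count and estimator are this
package's documented convention; with a few dozen conditions the plug-in
bias is about (bins−1)²/(2n) nats.

**Regulation.** Ternary calls per TF-mutant vs reference comparison: +1 if
log2FC ≥ 1 with adjusted p < 0.05, −1 if log2FC ≤ −1 with adjusted p < 0.05,
else 0 (thresholds configurable; precomputed ternary tables pass through
unchanged). Promoters are the ≤ 1000 bp immediately 5′ of the translation
start (1-based closed GFF coordinates, reverse-complemented on the minus
strand, truncated at contig edges with a warning). Motif counts use exact
IUPAC matching with overlaps allowed, summing forward-motif and
reverse-complement-motif matches on the promoter strand; palindromic motifs
therefore count twice per site, and an N in the sequence never matches.

**Biochemical.** Protein length, isoelectric point and Pfam-domain count are
consumed from a table. A blank pI falls back to computation from the
sequence: the root of the Henderson–Hasselbalch net charge on pH ∈ [0, 14],
found by bisection to 1e−3, with the EMBOSS pKa set (N-terminus 8.6,
C-terminus 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1). The net
charge is strictly decreasing in pH, so bisection always converges.

## Feature selection

Features are held in a canonical order — category order evolutionary →
expression → regulation → biochemical, alphabetical within category — which
fixes the tie-break of the greedy redundancy filter: scanning in order, a
feature is dropped iff its |PCC| with an already-kept feature exceeds 0.7.
Absolute correlation is used deliberately (a strong negative duplicate is
equally redundant even though the published rule is stated for positive
correlation). Constant features, whose correlation is undefined, are kept
with a warning.

RFE wraps a random forest: per iteration, the cross-validated F1 of the
current subset is recorded (stratified folds, majority class down-sampled
inside each training fold) and the single least-important feature (first
minimum on ties) is dropped; the best-scoring subset size wins, preferring
the smaller size on ties. Importance is mean impurity decrease, reported
sorted descending; it is defined only for forest models.

## Model training and evaluation

Six families run through one harness: random forest, RBF SVM, gradient
boosting, elastic-net logistic regression (standing in for GLMnet, with a
small C grid in place of a lambda path), kNN and Gaussian naive Bayes.
Scale-sensitive families are standardized inside the estimator pipeline.
Default grid spaces are compact (RF: 250/500/1000 trees × mtry fractions
0.1/0.33/0.5; SVM: C 0.1/1/10 × gamma scale/0.01; GBM: depth 2/3 × learning
rate 0.05/0.1 × 100/300 trees; elastic net: l1_ratio 0/0.5/1 × C
0.01/0.1/1/10; kNN: k 3/5/7/11; NB: none) and fully configurable.

Nested CV uses stratified folds: 5 inner folds score each grid point (by F1
at the 0.5 threshold by default — accuracy is degenerate for a rare class;
PR-AUC is available), the winner is refit on the balanced outer-training set
and evaluated on the untouched outer test fold; 3 outer folds give the mean
and population SD of each metric. Balancing happens strictly inside training
partitions — inner-fold training sets during tuning, the outer-training set
for the refit — never on test data. Grid ties go to the first point in
sorted-key product order; a single-point grid skips the inner loop. Down:
majority sampled without replacement to the minority size (every minority
sample kept exactly once). Over: minority resampled with replacement. SMOTE:
synthetic minority points x₀ + u·(x₁ − x₀), u ~ U(0, 1), with x₁ one of the
k = 5 nearest minority neighbours.

Metrics follow the standard confusion-table formulas (accuracy, specificity,
recall, precision, F1) at a strict 0.5 score threshold; zero denominators
yield 0 with a flag rather than an exception. PR-AUC is the step-wise
average-precision estimator, which handles tied scores in blocks. Note that
with only a handful of positives per fold average precision is biased upward
even for a random ranking (≈ 0.28 at 6 positives in 30 samples, against a
prevalence of 0.2); null-hypothesis checks must therefore run at sample
sizes where the bias is small relative to the tolerance.

For strict leakage-free evaluation of the *reference-anchored* features,
`nested_cv` accepts a `feature_builder` callback
(`pipeline.fold_feature_builder`) that recomputes co-occurrence and
co-expression features per outer fold using only that fold's training
positives as references. The operational no-leakage check is the permutation
test: with labels permuted, nested-CV PR-AUC collapses to prevalence.

The final model is refit on the whole balanced training partition with the
chosen grid point and persists as JSON metadata plus a joblib artifact;
reloading reproduces identical scores.

## Genome-wide prediction

Every secretome gene is scored; records carry the score, the predicted label
(score > 0.5, strict), the confidence tier (high for score > 0.7, low for
(0.5, 0.7], none otherwise — both boundaries strict and frozen in tests) and
the known status from the labels (characterized, previously predicted,
novel). Output is sorted by score descending with gene id as tie-break, so
re-runs are byte-identical.

## Synthetic data generator

The generator emulates the statistical structure of the curated benchmark so
that every stage, and end-to-end recovery, runs with no external data.
Defaults: 40 positives (80 % labelled characterized/train, 20 %
predicted/test, mirroring the 37:9 benchmark proportion), 300 negatives in
the five categories at the published proportions (the published per-category
counts sum to slightly more than the stated negative total, so only the
proportions are used), 10 species, 40 conditions, 7 TF comparisons, seed 0.

Signal is planted in exactly the channels that dominate the real problem's
feature-importance ranking — co-expression with known pectinases, pI,
regulation by the pectin TFs, expression on pectin substrates:

* **Expression.** Background: gene baseline ~ N(5, 1.5) plus N(0, noise_sd)
  per condition (log-scale values). Positives additionally load on one shared
  condition factor f_c ~ N(0, 1) with loading a = noise_sd·√(ρ/(1−ρ)),
  ρ = `coexpr_strength`, chosen so the *expected pairwise PCC between two
  positives equals ρ* — the knob is directly interpretable and ρ = 0 is
  exactly null. Positives also get a mean up-shift of 2ρ on the "pectin"
  condition block (the first quarter of conditions).
* **Phylogenetic profiles.** Background presence is i.i.d. Bernoulli(0.5)
  per species; positives match a common template per species with
  probability s = `profile_similarity`, realized as a template/background
  mixture with weight 2s−1, so s = 0.5 degenerates to the background law.
  The focal-species column is always 1.
* **Regulation.** Responsiveness (a non-zero call) has the same probability
  for both classes (0.6 under pectin-TF comparisons, 0.3 otherwise); only
  the *sign* carries signal: positives respond in the concordant direction
  (down under activator deletion gaaR/araR/rhaR, up under repressor deletion
  gaaX) with probability `regulation_concordance`, negatives uniformly —
  concordance 0.5 is exactly null.
* **Promoters.** Random 1000-mers with Poisson-planted motif copies; pectin-TF
  motifs are planted at `motif_enrichment` × the background rate (0.4 per
  promoter) in positives. Enrichment 1 is null.
* **pI.** N(6, 1.3) clipped to [3, 12], shifted by `pi_shift` (default −1,
  reflecting the acidic bias of secreted pectinases) for positives.

Length and Pfam count are class-independent by design (realistic
non-informative features); every synthetic gene carries a secretion flag so
the prediction universe is the whole gene set. Same seed ⇒ byte-identical
files.

What the generator does *not* emulate: realistic genome sequence,
tree-structured presence/absence evolution, correlated condition structure
beyond one factor, batch effects, or annotation noise in the labels. Passing
the recovery tests therefore demonstrates the pipeline's correctness and
leakage-freedom under a known ground truth, not field performance on real
fungal data; on the default conditions the planted signal is strong enough
that the outer-fold metrics saturate near 1.

## Problem sizes used in the automated checks

The test suite runs the full pipeline at the generator's default scale
(340 genes, 25 features) for signal-recovery, permutation-null and
importance checks (10 seeds where a seed-average is asserted), a reduced
scale (120 genes, 24 conditions) for the co-expression Monte-Carlo and
effect-size monotonicity sweeps, and a dedicated 5-informative/20-noise
design for RFE retention. These sizes are the package's own choice of desk
scale; the tested properties are size-stable.

## Known limitations

* The mutual-information estimator and bin count are a convention of this
  package; other estimators (k-NN, shrinkage) would change absolute MI
  values, though ranks are similar.
* The elastic-net family optimizes a fixed C grid rather than a regularization
  path.
* PR-AUC small-sample bias (above) makes outer folds with very few positives
  optimistic; prefer F1 or larger folds when positives are ≪ 10 per fold.
* Motif counting is exact IUPAC matching; no PWM scores, no mismatches.
* The redundancy filter is greedy and order-dependent by design; a different
  canonical order keeps different representatives of a correlated block.
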