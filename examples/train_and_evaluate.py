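"""Nested cross-validation of classifier families on the training partition,
then an independent test on the held-out partition.

The outer CV (3 folds) estimates generalization; the inner CV (5 folds) tunes
hyperparameters; each training partition is rebalanced by down-sampling before
fitting, and the outer test folds are never touched by balancing or tuning.
"""

import numpy as np

from pectiml import (
    CVConfig, ModelSpec, SyntheticConfig, fit_final, generate, nested_cv,
)
from pectiml.pipeline import Dataset, build_feature_table
from pectiml.training import evaluate_scores

dataset = Dataset.from_synthetic(generate(SyntheticConfig(seed=1)))
table = build_feature_table(dataset)
X, y = dataset.training_frame(table)
y = np.asarray(y)

specs = {
    "RF": ModelSpec("RF", {"n_estimators": [300], "max_features": [0.1, 0.33, 0.5]}),
    "kNN": ModelSpec("kNN", {"n_neighbors": [3, 5, 7]}),
    "NB": ModelSpec("NB"),
}
results = {}
for name, spec in specs.items():
    res = nested_cv(X, y, spec, CVConfig(seed=1))
    results[name] = res
    mean, std = res.mean(), res.std()
    print(f"{name:4s} nested CV: " + "  ".join(
        f"{k}={mean[k]:.3f}±{std[k]:.3f}" for k in ("ACC", "SP", "Recall", "F1", "PR_AUC")))

# refit the forest on the full training partition and score the held-out test set
best = results["RF"].chosen_params[0]
model = fit_final(X, y, specs["RF"], best, balancing="down", seed=1)
lab = dataset.labels.set_index("gene_id")
test_genes = [g for g in table.genes if lab.loc[g, "partition"] == "test"]
y_test = np.array([1 if lab.loc[g, "label"] == "positive" else 0 for g in test_genes])
m = evaluate_scores(model.predict_scores(table.values.loc[test_genes]), y_test)
print(f"\nindependent test ({len(test_genes)} genes, {y_test.sum()} positives): "
      f"ACC={m.ACC:.3f} SP={m.SP:.3f} Recall={m.Recall:.3f} "
      f"Precision={m.Precision:.3f} F1={m.F1:.3f}")
print("high specificity with good recall means the model rediscovers the "
      "held-out planted pectinases without flooding the candidate list")
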