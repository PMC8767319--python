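"""Class balancing, evaluation metrics and nested cross-validation."""

import numpy as np
import pytest

from pectiml import (
    CVConfig,
    ModelSpec,
    balance,
    compute_metrics,
    fit_final,
    nested_cv,
    pr_auc,
)
from pectiml.synthetic import make_planted_features
from pectiml.training import confusion_counts, evaluate_scores, make_estimator


def imbalanced(n_min=37, n_maj=233, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_min + n_maj, dim))
    y = np.array([1] * n_min + [0] * n_maj)
    return X, y


class TestBalance:
    def test_down_sampling_counts(self):
        X, y = imbalanced()
        Xb, yb = balance(X, y, "down", seed=0)
        assert (yb == 1).sum() == (yb == 0).sum() == 37

    def test_down_sampling_preserves_every_minority_sample(self):
        X, y = imbalanced(n_min=11, n_maj=40)
        Xb, yb = balance(X, y, "down", seed=3)
        minority_rows = {tuple(r) for r in X[y == 1]}
        kept = [tuple(r) for r in Xb[yb == 1]]
        assert sorted(kept) == sorted(minority_rows)

    def test_over_sampling_counts(self):
        X, y = imbalanced()
        Xb, yb = balance(X, y, "over", seed=0)
        assert (yb == 1).sum() == (yb == 0).sum() == 233
        # every over-sampled row is a copy of a real minority row
        minority_rows = {tuple(r) for r in X[y == 1]}
        assert all(tuple(r) in minority_rows for r in Xb[yb == 1])

    def test_smote_points_lie_on_minority_segments(self):
        X, y = imbalanced(n_min=12, n_maj=60, dim=2, seed=1)
        Xb, yb = balance(X, y, "smote", seed=1)
        assert (yb == 1).sum() == (yb == 0).sum() == 60
        minority = X[y == 1]
        synth = Xb[len(X):]
        for p in synth:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    t = float((p - minority[i]) @ d) / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.allclose(minority[i] + t * d, p, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_smote_needs_two_minority_samples(self):
        X, y = imbalanced(n_min=1, n_maj=10)
        with pytest.raises(ValueError):
            balance(X, y, "smote", seed=0)


class TestMetrics:
    def test_independent_test_worked_example(self):
        # 9 test positives, 6 recalled; all 77 negatives correct
        m = compute_metrics(tp=6, tn=77, fp=0, fn=3)
        assert m.Recall == pytest.approx(2 / 3)
        assert m.SP == pytest.approx(1.0)
        assert m.Precision == pytest.approx(1.0)
        assert m.ACC == pytest.approx(83 / 86)

    def test_f1_equals_p_when_precision_equals_recall(self):
        m = compute_metrics(tp=8, tn=10, fp=2, fn=2)  # precision = recall = 0.8
        assert m.F1 == pytest.approx(0.8)

    def test_zero_denominators_flagged_not_raised(self):
        m = compute_metrics(tp=0, tn=5, fp=0, fn=0)
        assert m.Precision == 0.0 and m.Recall == 0.0
        assert "Precision" in m.zero_denominator_flags

    def test_confusion_counts(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        assert confusion_counts(y, p) == (2, 1, 1, 1)


class TestPRAUC:
    def test_perfect_ranking(self):
        assert pr_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_step_curve_example(self):
        got = pr_auc(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0]))
        assert got == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_matches_hand_coded_step_estimator(self, rng):
        def oracle(scores, labels):
            order = np.argsort(-scores, kind="stable")
            lab = labels[order]
            tp = np.cumsum(lab)
            prec = tp / np.arange(1, len(lab) + 1)
            return float(np.sum(prec * lab) / lab.sum())

        for _ in range(20):
            scores = rng.random(50)  # distinct with probability 1
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            assert pr_auc(scores, labels) == pytest.approx(oracle(scores, labels), abs=1e-12)

    def test_random_scores_approach_prevalence(self, rng):
        labels = (rng.random(10000) < 0.2).astype(int)
        scores = rng.random(10000)
        assert pr_auc(scores, labels) == pytest.approx(0.2, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_auc(np.array([0.5, 0.6]), np.array([1, 1]))


class TestNestedCV:
    def test_outer_folds_are_stratified_partition(self):
        table, y, _ = make_planted_features(n_pos=30, n_neg=240, seed=0)  # 270 genes
        res = nested_cv(table, y, ModelSpec("NB"), CVConfig(seed=0))
        assert len(res.per_fold) == 3
        # each metric set came from a fold of size 90 with both classes present
        for m in res.per_fold:
            assert m.PR_AUC is not None

    def test_deterministic_for_fixed_seed(self):
        table, y, _ = make_planted_features(n_pos=20, n_neg=60, seed=2)
        spec = ModelSpec("RF", {"n_estimators": [50], "max_features": [0.5]})
        a = nested_cv(table, y, spec, CVConfig(seed=7))
        b = nested_cv(table, y, spec, CVConfig(seed=7))
        assert a.mean() == b.mean() and a.chosen_params == b.chosen_params

    def test_planted_signal_recovered_by_forest(self):
        table, y, _ = make_planted_features(n_pos=30, n_neg=120, effect=2.0, seed=4)
        spec = ModelSpec("RF", {"n_estimators": [100], "max_features": [0.33, 0.5]})
        res = nested_cv(table, y, spec, CVConfig(seed=4))
        mean = res.mean()
        assert mean["Recall"] >= 0.7 and mean["SP"] >= 0.9

    def test_all_six_families_run_through_the_same_harness(self):
        table, y, _ = make_planted_features(n_pos=20, n_neg=60, effect=2.0, seed=6)
        for family in ("RF", "SVM", "GBM", "GLMnet", "kNN", "NB"):
            spec = ModelSpec(family, {k: v[:1] for k, v in ModelSpec(family).grid.items()})
            res = nested_cv(table, y, spec, CVConfig(seed=6))
            for m in res.per_fold:
                assert 0.0 <= m.ACC <= 1.0 and m.PR_AUC is not None

    def test_errors(self):
        table, y, _ = make_planted_features(n_pos=4, n_neg=4, seed=0)
        with pytest.raises(ValueError):
            nested_cv(table, np.zeros(8), ModelSpec("NB"), CVConfig(seed=0))
        with pytest.raises(ValueError):
            CVConfig(outer_folds=1)
        with pytest.raises(ValueError):
            CVConfig(balancing="none")
        with pytest.raises(ValueError):
            ModelSpec("MLP")


class TestFitFinal:
    def test_refit_same_seed_identical_predictions(self):
        table, y, _ = make_planted_features(seed=8)
        spec = ModelSpec("RF", {"n_estimators": [100]})
        a = fit_final(table, y, spec, {"n_estimators": 100}, "down", seed=8)
        b = fit_final(table, y, spec, {"n_estimators": 100}, "down", seed=8)
        probe = table.values.iloc[:20]
        assert (a.predict_scores(probe) == b.predict_scores(probe)).all()

    def test_persist_round_trip(self, tmp_path):
        from pectiml.training import TrainedModel

        table, y, _ = make_planted_features(seed=9)
        model = fit_final(table, y, ModelSpec("RF", {"n_estimators": [50]}),
                          {"n_estimators": 50}, "down", seed=9)
        model.save(tmp_path)
        loaded = TrainedModel.load(tmp_path)
        probe = table.values.iloc[:25]
        assert (model.predict_scores(probe) == loaded.predict_scores(probe)).all()
        assert loaded.hyperparams == {"n_estimators": 50}

    def test_scores_in_unit_interval_for_all_families(self):
        table, y, _ = make_planted_features(n_pos=15, n_neg=45, seed=10)
        for family in ("RF", "SVM", "GBM", "GLMnet", "kNN", "NB"):
            params = {k: v[0] for k, v in ModelSpec(family).grid.items()}
            model = fit_final(table, y, ModelSpec(family, {k: [v] for k, v in params.items()} or {}),
                              params, "down", seed=10)
            s = model.predict_scores(table.values)
            assert ((s >= 0) & (s <= 1)).all()

    def test_held_out_planted_positive_scores_high(self):
        wins = 0
        for seed in range(10):
            table, y, _ = make_planted_features(n_pos=21, n_neg=60, effect=2.0, seed=seed)
            hold = table.values.index[0]  # a planted positive
            rest = table.values.index[1:]
            sub = table.subset(table.feature_names)
            model = fit_final(sub.values.loc[rest], y[1:],
                              ModelSpec("RF", {"n_estimators": [100]}),
                              {"n_estimators": 100}, "down", seed=seed)
            wins += model.predict_scores(table.values.loc[[hold]]).iloc[0] > 0.5
        assert wins >= 8


def test_evaluate_scores_threshold_is_strict():
    scores = np.array([0.5, 0.6, 0.4, 0.7])
    labels = np.array([0, 1, 0, 1])
    m = evaluate_scores(scores, labels)
    # 0.5 is not a positive call
    assert m.Recall == 1.0 and m.SP == 1.0


def test_strict_cv_feature_builder_hook():
    """The feature_builder callback is invoked per outer fold and its output
    is used for that fold's fit and evaluation."""
    table, y, _ = make_planted_features(n_pos=20, n_neg=60, seed=11)
    calls = []

    def builder(train_genes):
        calls.append(sorted(train_genes))
        return table.values

    res = nested_cv(table, y, ModelSpec("NB"), CVConfig(seed=11), feature_builder=builder)
    assert len(calls) == 3
    assert all(len(c) < len(y) for c in calls)
    assert len(res.per_fold) == 3
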