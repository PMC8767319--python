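"""Feature-table assembly, redundancy filtering, RFE and importance ranking."""

import numpy as np
import pandas as pd
import pytest

from pectiml import (
    FeatureTable,
    assemble_feature_table,
    fit_final,
    importance_ranking,
    redundancy_filter,
    rfe_select,
)
from pectiml.synthetic import make_planted_features
from pectiml.training import ModelSpec


def make_table(cols: dict, category="expression"):
    values = pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))])
    return FeatureTable(values, {c: category for c in cols})


class TestFeatureTable:
    def test_rejects_na_and_duplicates(self, rng):
        with pytest.raises(ValueError, match="missing"):
            make_table({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        values = pd.DataFrame(rng.normal(size=(3, 2)), columns=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(values, {"a": "expression"})

    def test_canonical_order_category_then_alphabetical(self, rng):
        values = pd.DataFrame(rng.normal(size=(4, 4)), columns=["z_bio", "a_reg", "m_evo", "b_evo"])
        meta = {"z_bio": "biochemical", "a_reg": "regulation", "m_evo": "evolutionary", "b_evo": "evolutionary"}
        t = FeatureTable(values, meta).canonical_order()
        assert t.feature_names == ["b_evo", "m_evo", "a_reg", "z_bio"]

    def test_assemble_joins_on_common_genes(self, rng):
        evo = pd.DataFrame(rng.normal(size=(4, 2)), index=list("abcd"), columns=["e1", "e2"])
        bio = pd.DataFrame(rng.normal(size=(3, 1)), index=list("abc"), columns=["b1"])
        t = assemble_feature_table({"evolutionary": evo, "biochemical": bio})
        assert t.genes == list("abc")
        assert t.feature_names == ["e1", "e2", "b1"]


class TestRedundancyFilter:
    def test_greedy_keeps_first_of_correlated_pair(self, rng):
        a = rng.normal(size=200)
        b = a + 0.1 * rng.normal(size=200)  # |PCC| > 0.9
        c = rng.normal(size=200)
        res = redundancy_filter(make_table({"a": a, "b": b, "c": c}))
        assert res.kept_features == ["a", "c"]
        dropped, partner, r = res.dropped_redundant[0]
        assert (dropped, partner) == ("b", "a") and r > 0.9

    def test_uncorrelated_features_all_kept(self, rng):
        x = rng.normal(size=(300, 4))
        res = redundancy_filter(make_table({f"f{i}": x[:, i] for i in range(4)}))
        assert res.kept_features == [f"f{i}" for i in range(4)]

    def test_three_mutual_duplicates_keep_first(self, rng):
        a = rng.normal(size=100)
        res = redundancy_filter(make_table({"a": a, "b": a * 2, "c": -a}))
        assert res.kept_features == ["a"]

    def test_strong_negative_correlation_is_redundant(self, rng):
        a = rng.normal(size=100)
        res = redundancy_filter(make_table({"a": a, "b": -a + 0.05 * rng.normal(size=100)}))
        assert res.kept_features == ["a"]

    def test_no_kept_pair_exceeds_threshold(self, rng):
        base = rng.normal(size=(150, 3))
        cols = {}
        for i in range(9):  # correlated triples
            cols[f"f{i}"] = base[:, i % 3] + 0.4 * rng.normal(size=150)
        res = redundancy_filter(make_table(cols), threshold=0.7)
        kept = [cols[f] for f in res.kept_features]
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert abs(np.corrcoef(kept[i], kept[j])[0, 1]) <= 0.7

    def test_constant_feature_kept_with_warning(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            res = redundancy_filter(make_table({"a": np.ones(50), "b": rng.normal(size=50)}))
        assert res.kept_features == ["a", "b"]


class TestRFE:
    def test_two_complementary_informative_features_both_retained(self):
        # each feature separates only half the positives, so dropping either
        # one strictly hurts and RFE must keep both
        rng = np.random.default_rng(0)
        n_pos, n_neg = 30, 60
        X = rng.normal(size=(n_pos + n_neg, 2))
        X[: n_pos // 2, 0] += 4.0
        X[n_pos // 2 : n_pos, 1] += 4.0
        y = np.array([1] * n_pos + [0] * n_neg)
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(len(y))], columns=["f1", "f2"])
        table = FeatureTable(values, {"f1": "expression", "f2": "expression"})
        res = rfe_select(table, y, seed=0, rf_params={"n_estimators": 100})
        assert set(res.rfe_selected) == {"f1", "f2"}

    def test_recovers_planted_informative_features(self):
        table, y, informative = make_planted_features(seed=3)
        res = rfe_select(table, y, seed=3, rf_params={"n_estimators": 100})
        assert len(set(res.rfe_selected) & set(informative)) >= 4
        assert set(res.rfe_selected) <= set(table.feature_names)

    def test_permuted_labels_score_near_prevalence_baseline(self, rng):
        table, y, _ = make_planted_features(n_pos=30, n_neg=60, seed=5)
        yp = rng.permutation(y)
        res = rfe_select(table, yp, seed=5, rf_params={"n_estimators": 100})
        # F1 of a prevalence-rate guess on a balanced-recall classifier is bounded
        assert max(res.cv_scores.values()) < 0.65

    def test_single_class_rejected(self):
        table, y, _ = make_planted_features(n_pos=5, n_neg=5, seed=0)
        with pytest.raises(ValueError):
            rfe_select(table, np.zeros_like(y), seed=0)


class TestImportance:
    def test_planted_feature_ranks_first(self):
        table, y, informative = make_planted_features(
            n_pos=40, n_neg=80, n_informative=1, n_noise=10, effect=2.5, seed=1
        )
        model = fit_final(table, y, ModelSpec("RF", {"n_estimators": [200]}),
                          {"n_estimators": 200}, "down", seed=1)
        ranking = importance_ranking(model, table)
        assert next(iter(ranking)) == informative[0]
        assert sum(ranking.values()) > 0
        assert all(v >= 0 for v in ranking.values())

    def test_non_forest_model_rejected(self):
        table, y, _ = make_planted_features(n_pos=10, n_neg=20, seed=0)
        model = fit_final(table, y, ModelSpec("NB"), {}, "down", seed=0)
        with pytest.raises(TypeError):
            importance_ranking(model, table)
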