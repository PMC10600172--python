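import logging

import numpy as np
import pandas as pd
import pytest

from damscore.classify import BehaviorClassifier, RFHyperparams
from damscore.explain import (
    attribution_category_sums,
    category_mean_rank,
    forest_attributions,
    permutation_importance,
    sample_attributions,
)
from damscore.features.manifest import FeatureEntry, FeatureManifest, default_manifest


@pytest.fixture(scope="module")
def toy_model():
    """Two-feature model: one perfectly informative, one pure noise."""
    rng = np.random.default_rng(0)
    n = 600
    y = np.arange(n) % 2 == 0
    X = pd.DataFrame({
        "signal": y.astype(float) + rng.normal(0, 0.05, n),
        "noise": rng.normal(size=n),
    })
    res = BehaviorClassifier(X, y, "toy", RFHyperparams(n_trees=100, seed=0)).fit()
    return X, y, res


@pytest.fixture(scope="module")
def toy_manifest():
    return FeatureManifest(entries=(
        FeatureEntry("signal", "dam_location", "px"),
        FeatureEntry("noise", "dam_movement", "mm"),
    ))


class TestPermutationImportance:
    def test_informative_feature_ranks_first(self, toy_model):
        X, y, res = toy_model
        table = permutation_importance(res, X, y, n_repeats=20, seed=1)
        assert table.set_index("feature_name").loc["signal", "rank"] == 1

    def test_noise_feature_importance_near_zero(self, toy_model):
        X, y, res = toy_model
        table = permutation_importance(res, X, y, n_repeats=20, seed=1)
        noise = table.set_index("feature_name").loc["noise", "importance_score"]
        assert abs(noise) < 0.02

    def test_exact_ties_broken_by_column_order(self, toy_model):
        X, y, res2 = toy_model
        # two constant columns are untouched by shuffling: importance exactly 0
        Xc = pd.DataFrame({"a": np.ones(200), "b": np.ones(200)})
        yc = np.arange(200) % 2 == 0
        res = BehaviorClassifier(Xc, yc, "c", RFHyperparams(n_trees=100, seed=0)).fit()
        table = permutation_importance(res, Xc, yc, n_repeats=5, seed=0)
        t = table.set_index("feature_name")
        assert t.loc["a", "rank"] < t.loc["b", "rank"]

    def test_rank_vector_is_permutation(self, toy_model):
        X, y, res = toy_model
        table = permutation_importance(res, X, y, n_repeats=5, seed=0)
        assert sorted(table["rank"]) == list(range(1, len(X.columns) + 1))

    def test_single_class_rejected(self, toy_model):
        X, y, res = toy_model
        with pytest.raises(ValueError):
            permutation_importance(res, X, np.ones(len(X), bool))


class TestCategoryMeanRank:
    def test_hand_arithmetic(self, toy_manifest):
        table = pd.DataFrame({
            "feature_name": ["signal", "noise"],
            "importance_score": [0.9, 0.1],
            "rank": [1, 2],
        })
        ranks = category_mean_rank(table, toy_manifest)
        assert ranks["dam_location"] == 1.0
        assert ranks["dam_movement"] == 2.0

    def test_mean_of_all_ranks_is_rank_sum_identity(self):
        m = default_manifest()
        table = pd.DataFrame({
            "feature_name": m.names,
            "importance_score": np.zeros(len(m)),
            "rank": np.arange(1, len(m) + 1),
        })
        ranks = category_mean_rank(table, m)
        sizes = {c: len(v) for c, v in m.by_category().items()}
        overall = sum(ranks[c] * sizes[c] for c in sizes) / len(m)
        assert overall == pytest.approx((len(m) + 1) / 2)  # 109.5

    def test_row_order_irrelevant(self, toy_manifest):
        table = pd.DataFrame({
            "feature_name": ["noise", "signal"],
            "importance_score": [0.1, 0.9],
            "rank": [2, 1],
        })
        ranks = category_mean_rank(table, toy_manifest)
        assert ranks["dam_location"] == 1.0

    def test_missing_feature_rejected(self, toy_manifest):
        table = pd.DataFrame({
            "feature_name": ["signal"], "importance_score": [1.0], "rank": [1]})
        with pytest.raises(ValueError, match="missing"):
            category_mean_rank(table, toy_manifest)


class TestAttribution:
    def test_additivity_reconstructs_probability(self, toy_model):
        X, _, res = toy_model
        base, contrib = forest_attributions(res.model, X.to_numpy())
        reconstructed = base + contrib.sum(axis=1)
        np.testing.assert_allclose(reconstructed, res.predict_proba(X), atol=1e-9)

    def test_sample_sizes_150_when_available(self, toy_model):
        X, y, res = toy_model
        sample = sample_attributions(res, X, y, n_per_class=150, seed=0)
        assert len(sample.present_idx) == 150
        assert len(sample.absent_idx) == 150
        assert set(y[sample.present_idx]) == {True}
        assert set(y[sample.absent_idx]) == {False}

    def test_short_class_uses_all_with_warning(self, toy_model, caplog):
        X, y, res = toy_model
        with caplog.at_level(logging.WARNING):
            sample = sample_attributions(res, X.iloc[:40], y[:40], n_per_class=150, seed=0)
        assert len(sample.present_idx) == int(y[:40].sum())
        assert any("available" in r.message for r in caplog.records)

    def test_category_sums_plus_base_match_mean_probability(self, toy_model, toy_manifest):
        X, y, res = toy_model
        sample = sample_attributions(res, X, y, n_per_class=100, seed=3)
        sums = attribution_category_sums(sample, toy_manifest)
        n_p = len(sample.present_idx)
        mean_prob_present = sample.probabilities[:n_p].mean()
        assert sums["present"].sum() + sample.base_rate == pytest.approx(
            mean_prob_present, abs=1e-9
        )
        mean_prob_absent = sample.probabilities[n_p:].mean()
        assert sums["absent"].sum() + sample.base_rate == pytest.approx(
            mean_prob_absent, abs=1e-9
        )

    def test_signal_feature_separates_sign_by_class(self, toy_model, toy_manifest):
        X, y, res = toy_model
        sample = sample_attributions(res, X, y, n_per_class=100, seed=2)
        sums = attribution_category_sums(sample, toy_manifest)
        assert sums.loc["dam_location", "present"] > 0  # pushes probability up
        assert sums.loc["dam_location", "absent"] < 0
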