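import numpy as np
import pandas as pd
import pytest

from damscore.classify import (
    BehaviorClassifier,
    BehaviorClassifierResults,
    PRCurve,
    RFHyperparams,
    evaluate,
    merge_behaviors,
    pr_curve_from_probs,
    select_threshold,
    subsample_alternate_frames,
)


def _labels_with_scores(tp, fp, fn, tn=100):
    """Construct (pred, truth) vectors realizing an exact confusion matrix."""
    pred = np.concatenate([np.ones(tp + fp), np.zeros(fn + tn)]).astype(bool)
    truth = np.concatenate(
        [np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)]
    ).astype(bool)
    return pred, truth


class TestEvaluate:
    def test_merged_eating_drinking_worked_example(self):
        # precision 0.71, recall 0.69 -> F1 0.70 at 2 d.p.
        pred, truth = _labels_with_scores(tp=71 * 69, fp=69 * 29, fn=71 * 31)
        s = evaluate(pred, truth)
        assert s.precision == pytest.approx(0.71)
        assert s.recall == pytest.approx(0.69)
        assert round(s.f1, 2) == 0.70

    def test_perfect_prediction(self):
        y = np.array([True, False, True, False])
        assert evaluate(y, y) == (1.0, 1.0, 1.0)

    def test_all_negative_prediction_zeroes(self):
        s = evaluate(np.zeros(5, bool), np.array([1, 0, 1, 0, 0], bool))
        assert s == (0.0, 0.0, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [1])

    def test_agrees_with_bruteforce_confusion_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(1, 10_000))
            pred = rng.random(n) < 0.4
            truth = rng.random(n) < 0.3
            s = evaluate(pred, truth)
            tp = sum(bool(p) and bool(t) for p, t in zip(pred, truth))
            fp = sum(bool(p) and not t for p, t in zip(pred, truth))
            fn = sum(not p and bool(t) for p, t in zip(pred, truth))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert s.precision == pytest.approx(prec)
            assert s.recall == pytest.approx(rec)


class TestMergeBehaviors:
    def test_elementwise_or(self):
        np.testing.assert_array_equal(
            merge_behaviors([1, 0, 0], [0, 1, 0]), [True, True, False]
        )

    def test_idempotent_and_identity(self):
        x = np.array([1, 0, 1], bool)
        np.testing.assert_array_equal(merge_behaviors(x, x), x)
        np.testing.assert_array_equal(merge_behaviors(x, np.zeros(3, bool)), x)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            merge_behaviors([1], [1, 0])


class TestSubsample:
    def test_keeps_even_indices(self):
        X = pd.DataFrame({"f": np.arange(100.0)})
        Xs, ys = subsample_alternate_frames(X, np.zeros(100))
        assert len(Xs) == 50
        np.testing.assert_array_equal(Xs["f"].to_numpy(), np.arange(0, 100, 2.0))

    def test_per_video_indexing(self):
        X = pd.DataFrame({"f": np.arange(20.0)})
        vids = np.array(["a"] * 10 + ["b"] * 10)
        Xs, _ = subsample_alternate_frames(X, np.zeros(20), video_ids=vids)
        assert len(Xs) == 10
        # frame 10 is frame 0 of video b, so it must be kept
        assert 10.0 in set(Xs["f"])

    def test_single_frame_video_kept(self):
        Xs, _ = subsample_alternate_frames(pd.DataFrame({"f": [1.0]}), [0])
        assert len(Xs) == 1

    def test_misaligned_lengths(self):
        with pytest.raises(ValueError):
            subsample_alternate_frames(pd.DataFrame({"f": [1.0, 2.0]}), [0])


def _blobs(n=2000, d=218, sep=10.0, seed=7):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2 == 0
    X = rng.normal(size=(n, d))
    X[y, 0] += sep
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(d)]), y


class TestTraining:
    def test_separable_blobs_reach_perfect_f1(self):
        X, y = _blobs()
        res = BehaviorClassifier(X, y, "toy", RFHyperparams(n_trees=100, seed=7)).fit()
        assert res.training_stats["test_f1"] == 1.0

    def test_shuffled_labels_give_chance_level_f1(self):
        X, y = _blobs(n=1000, sep=0.0, seed=11)
        res = BehaviorClassifier(X, y, "null", RFHyperparams(n_trees=100, seed=11)).fit()
        # with no signal, F1 cannot rise far above the positive base rate
        assert res.training_stats["test_f1"] < y.mean() + 0.2

    def test_single_class_labels_error_names_behavior(self):
        X, _ = _blobs(n=50)
        with pytest.raises(ValueError, match="licking_grooming"):
            BehaviorClassifier(X, np.ones(50, bool), "licking_grooming").fit()

    def test_determinism_given_seed(self):
        X, y = _blobs(n=400)
        hp = RFHyperparams(n_trees=100, seed=3)
        a = BehaviorClassifier(X, y, "t", hp).fit()
        b = BehaviorClassifier(X, y, "t", hp).fit()
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.predict(X)[0], b.predict(X)[0])

    def test_hyperparam_ranges_enforced(self):
        with pytest.raises(ValueError):
            RFHyperparams(n_trees=50)
        with pytest.raises(ValueError):
            RFHyperparams(min_leaf=3)

    def test_save_load_round_trip(self, tmp_path):
        X, y = _blobs(n=300)
        res = BehaviorClassifier(X, y, "t", RFHyperparams(n_trees=100, seed=0)).fit()
        res.save(tmp_path / "bundle")
        back = BehaviorClassifierResults.load(tmp_path / "bundle")
        assert back.threshold == res.threshold
        assert back.behavior == res.behavior
        np.testing.assert_array_equal(back.predict(X)[1], res.predict(X)[1])

    def test_summary_mentions_key_quantities(self):
        X, y = _blobs(n=300)
        res = BehaviorClassifier(X, y, "t", RFHyperparams(n_trees=100, seed=0)).fit()
        text = res.summary()
        assert "threshold" in text and "test F1" in text


class TestPRCurve:
    def test_perfect_probabilities(self):
        probs = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([1, 1, 0, 0], bool)
        c = pr_curve_from_probs(probs, labels)
        inner = (c.thresholds > 0) & (c.thresholds < 1)
        assert (c.precision[inner] == 1).all() and (c.recall[inner] == 1).all()

    def test_threshold_zero_gives_full_recall(self):
        c = pr_curve_from_probs(np.array([0.2, 0.8]), np.array([1, 0], bool))
        assert c.recall[c.thresholds == 0][0] == 1.0

    def test_toy_confusion_at_half(self):
        probs = np.array([0.9, 0.6, 0.4, 0.1])
        labels = np.array([1, 1, 0, 0], bool)
        s = evaluate(probs >= 0.5, labels)
        assert s == (1.0, 1.0, 1.0)

    def test_no_positive_labels_rejected(self):
        with pytest.raises(ValueError, match="recall"):
            pr_curve_from_probs(np.array([0.5]), np.array([0], bool))

    def test_recall_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            probs = rng.random(500)
            labels = rng.random(500) < 0.3
            c = pr_curve_from_probs(probs, labels)
            assert (np.diff(c.recall) <= 1e-12).all()


class TestSelectThreshold:
    def _curve(self, thresholds, f1):
        t = np.asarray(thresholds, float)
        z = np.zeros_like(t)
        return PRCurve(t, z, z, np.asarray(f1, float))

    def test_unique_maximum(self):
        t, prov = select_threshold(self._curve([0.1, 0.5, 0.9], [0.2, 0.8, 0.3]))
        assert (t, prov) == (0.5, "max_f1")

    def test_plateau_takes_smallest(self):
        t, _ = select_threshold(self._curve([0.2, 0.3, 0.4, 0.5], [0.1, 0.9, 0.9, 0.9]))
        assert t == 0.3

    def test_manual_override_recorded(self):
        t, prov = select_threshold(self._curve([0.5], [0.5]), override=0.45)
        assert (t, prov) == (0.45, "manual")

    def test_all_nan_f1_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(self._curve([0.1, 0.2], [np.nan, np.nan]))


@pytest.fixture(scope="module")
def fitted():
    X, y = _blobs(n=300)
    return X, BehaviorClassifier(X, y, "t", RFHyperparams(n_trees=100, seed=0)).fit()


class TestPredict:
    def test_probability_at_threshold_is_positive(self, fitted):
        X, res = fitted
        probs, labels = res.predict(X)
        at = probs >= res.threshold
        np.testing.assert_array_equal(labels, at)

    def test_manifest_version_mismatch_names_both(self, fitted, fm_and_labels):
        _, res = fitted
        fm = fm_and_labels[0]
        res.manifest_version = "0-other"
        try:
            with pytest.raises(ValueError, match="0-other"):
                res.predict(fm)
        finally:
            res.manifest_version = "1"
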