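"""Feature registry, metrics, grid search, bootstrap, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import GridSearchCV

from cogscreen.bench import (
    FEATURE_SPACES,
    MODEL_ZOO,
    ModelSpec,
    bootstrap_evaluate,
    build_feature_matrix,
    evaluate,
    grid_search_train,
    kmeans_elbow,
    split_cohort,
)


def auc_oracle(scores, labels):
    """Pairwise concordance with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestFeatureRegistry:
    @pytest.mark.parametrize(
        "name,size",
        [("F1", 13), ("F2", 9), ("F3", 10), ("F4", 6), ("F5", 9), ("F6", 7), ("F7", 3),
         ("F8", 1), ("F9", 1), ("F10", 1), ("F11", 2), ("F12", 1), ("F13", 3),
         ("F14", 3), ("F15", 2), ("F16", 5)],
    )
    def test_sizes(self, name, size):
        assert len(FEATURE_SPACES[name].features) == size

    def test_named_contents(self):
        assert FEATURE_SPACES["F15"].features == ("age", "SSHO2D")
        assert FEATURE_SPACES["F8"].features == ("Composite1",)
        assert FEATURE_SPACES["F7"].features == ("SSHO2D", "dccs2D", "psm2D")

    def test_build_orders_columns_and_errors_on_missing(self, rng):
        df = pd.DataFrame({"SSHO2D": rng.normal(size=5), "age": rng.integers(67, 94, 5)})
        X = build_feature_matrix(df, "F15")
        assert list(X.columns) == ["age", "SSHO2D"]
        with pytest.raises(ValueError, match="F7"):
            build_feature_matrix(df, "F7")


class TestSplit:
    def test_reference_cohort_sizes(self):
        labels = np.array([1] * 19 + [0] * 67)
        train, test = split_cohort(86, 0.8, seed=0, labels=labels)
        assert (len(train), len(test)) == (68, 18)
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == 86

    def test_small_cohort_sizes(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 1, 0])
        train, test = split_cohort(10, 0.8, seed=0, labels=labels)
        assert (len(train), len(test)) == (8, 2)

    def test_stratification_preserves_both_classes(self):
        labels = np.array([1] * 19 + [0] * 67)
        train, test = split_cohort(86, 0.8, seed=5, labels=labels)
        assert 0 < labels[train].sum() < len(train)
        assert 0 < labels[test].sum() < len(test)

    def test_same_seed_same_split(self):
        labels = (np.arange(40) % 4 == 0).astype(int)
        s1 = split_cohort(40, 0.8, seed=9, labels=labels)
        s2 = split_cohort(40, 0.8, seed=9, labels=labels)
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(10, 1.5, 0, np.zeros(10))


class TestEvaluate:
    def test_worked_confusion_example(self):
        # TP=3, FP=1, FN=2, TN=12
        labels = np.array([1] * 5 + [0] * 13)
        preds = np.array([1, 1, 1, 0, 0] + [1] + [0] * 12)
        res = evaluate(preds, labels)
        assert (res.confusion.tp, res.confusion.fp, res.confusion.fn, res.confusion.tn) == (3, 1, 2, 12)
        assert res.precision == pytest.approx(0.75)
        assert res.recall == pytest.approx(0.6)
        assert res.accuracy == pytest.approx(15 / 18)
        assert res.specificity == pytest.approx(12 / 13)
        assert res.f_score == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_qwk_balanced_example(self):
        # confusion [[45, 5], [5, 45]]: agreement 0.9, chance 0.5 -> 0.8
        labels = np.array([0] * 50 + [1] * 50)
        preds = np.array([0] * 45 + [1] * 5 + [1] * 45 + [0] * 5)
        res = evaluate(preds, labels)
        assert res.qwk == pytest.approx(0.8)

    def test_auc_worked_example(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        res = evaluate(labels, labels, scores=scores)
        assert res.auc == pytest.approx(0.75)
        assert res.auc == pytest.approx(auc_oracle(scores, labels))

    def test_auc_matches_concordance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 51))
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)
            res = evaluate(labels, labels, scores=scores)
            assert res.auc == pytest.approx(auc_oracle(scores, labels))

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = (rng.random(30) < 0.4).astype(int)
        scores = rng.normal(size=30)
        a1 = evaluate(labels, labels, scores=scores).auc
        a2 = evaluate(labels, labels, scores=np.exp(scores)).auc
        assert a1 == pytest.approx(a2)

    def test_metric_identities_on_random_confusions(self, rng):
        for _ in range(100):
            labels = (rng.random(25) < rng.uniform(0.2, 0.8)).astype(int)
            preds = (rng.random(25) < rng.uniform(0.2, 0.8)).astype(int)
            res = evaluate(preds, labels)
            cm = res.confusion
            if cm.tp + cm.fp:
                assert res.precision == pytest.approx(cm.tp / (cm.tp + cm.fp), abs=1e-12)
            else:
                assert np.isnan(res.precision)
            if cm.tp + cm.fn:
                assert res.recall == pytest.approx(cm.tp / (cm.tp + cm.fn), abs=1e-12)
            if cm.tn + cm.fp:
                assert res.specificity == pytest.approx(cm.tn / (cm.tn + cm.fp), abs=1e-12)
            assert res.accuracy == pytest.approx((cm.tp + cm.tn) / cm.n, abs=1e-12)
            n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp
            if n_pos and n_neg:
                assert res.accuracy == pytest.approx(
                    (res.recall * n_pos + res.specificity * n_neg) / cm.n, abs=1e-12
                )

    def test_undefined_ratios_are_nan_not_zero(self):
        res = evaluate(np.zeros(6, int), np.zeros(6, int))
        assert np.isnan(res.precision)  # no predicted positives
        assert np.isnan(res.recall)  # no actual positives
        assert res.accuracy == 1.0

    def test_weighted_average_convention(self):
        labels = np.array([1] * 5 + [0] * 13)
        preds = np.array([1, 1, 1, 0, 0] + [1] + [0] * 12)
        res = evaluate(preds, labels, average="weighted")
        # weighted recall equals accuracy for binary labels
        assert res.recall == pytest.approx(res.accuracy)


class TestGridSearch:
    def test_zoo_grids_match_protocol(self):
        assert MODEL_ZOO["SVC"].grid["C"] == [1, 10, 50, 100]
        assert len(MODEL_ZOO["LRG"].grid["C"]) == 20
        assert min(MODEL_ZOO["LRG"].grid["C"]) == pytest.approx(0.01)
        assert max(MODEL_ZOO["LRG"].grid["C"]) == pytest.approx(5.0)
        assert len(MODEL_ZOO["Tree"].grid["max_depth"]) == 7
        assert len(MODEL_ZOO["RF"].grid["n_estimators"]) == 10
        assert (MODEL_ZOO["RF"].grid["n_estimators"][0], MODEL_ZOO["RF"].grid["n_estimators"][-1]) == (10, 500)
        assert MODEL_ZOO["GB"].grid["n_estimators"] == [10, 30, 50]
        assert len(MODEL_ZOO["ANN"].grid["alpha"]) == 3

    def test_one_point_grid_equals_plain_fit(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        spec = ModelSpec("Tree", {"max_depth": [3]})
        gs = grid_search_train(spec, X, y, seed=0)
        plain = spec.make_estimator(0).set_params(max_depth=3).fit(X, y)
        np.testing.assert_array_equal(gs.predict(X), plain.predict(X))

    def test_forest_shortcut_matches_gridsearchcv(self, rng):
        X = rng.normal(size=(50, 2))
        y = (rng.random(50) < 0.3).astype(int)
        fast = grid_search_train(MODEL_ZOO["RF"], X, y, seed=3)
        slow = GridSearchCV(
            MODEL_ZOO["RF"].make_estimator(3), MODEL_ZOO["RF"].grid, cv=5, scoring="accuracy"
        ).fit(X, y)
        assert fast.best_params_["n_estimators"] == slow.best_params_["n_estimators"]
        grid = MODEL_ZOO["RF"].grid["n_estimators"]
        np.testing.assert_allclose(
            [fast.cv_mean_accuracy_[k] for k in grid],
            slow.cv_results_["mean_test_score"],
            atol=1e-12,
        )

    def test_determinism(self, rng):
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.4).astype(int)
        g1 = grid_search_train(MODEL_ZOO["GB"], X, y, seed=7)
        g2 = grid_search_train(MODEL_ZOO["GB"], X, y, seed=7)
        assert g1.best_params_ == g2.best_params_

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            grid_search_train(MODEL_ZOO["Tree"], np.zeros((10, 1)), np.zeros(10))

    @pytest.mark.parametrize("name", list(MODEL_ZOO))
    def test_every_model_solves_separable_gaussians(self, name):
        rng = np.random.default_rng(42)
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(size=(n, 2)) + 6.0 * y[:, None]
        train, test = split_cohort(n, 0.8, seed=0, labels=y)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = grid_search_train(MODEL_ZOO[name], X[train], y[train], seed=0)
        acc = np.mean(est.predict(X[test]) == y[test])
        assert acc >= 0.95


class TestBootstrap:
    def test_label_leak_stub_gives_perfect_metrics(self):
        # feature == label: any tree reproduces the truth on every split
        y = np.array([0, 1] * 20)
        X = y[:, None].astype(float)
        summ = bootstrap_evaluate(X, y, ModelSpec("Tree", {"max_depth": [3]}), B=5, seed=0)
        for metric in ("precision", "recall", "accuracy", "specificity", "f_score"):
            assert summ.means[metric] == pytest.approx(1.0)
            assert summ.sds[metric] == pytest.approx(0.0)

    def test_single_replication_matches_direct_run(self, rng):
        from cogscreen.bench import _prediction_scores

        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.35).astype(int)
        spec = ModelSpec("Tree", {"max_depth": [3, 7]})
        seed = 21
        summ = bootstrap_evaluate(X, y, spec, B=1, seed=seed)
        # replay the replication independently
        rng2 = np.random.default_rng(seed)
        while True:
            take = rng2.integers(0, 40, size=40)
            if 0 < y[take].sum() < 40:
                break
        rep_seed = int(rng2.integers(0, 2**31 - 1))
        train, test = split_cohort(40, 0.8, rep_seed, y[take])
        est = grid_search_train(spec, X[take][train], y[take][train], seed=rep_seed)
        direct = evaluate(
            est.predict(X[take][test]), y[take][test], scores=_prediction_scores(est, X[take][test])
        )
        for metric, value in direct.as_dict().items():
            got = summ.means[metric]
            assert (np.isnan(got) and np.isnan(value)) or got == pytest.approx(value)

    def test_skip_counts_reported(self, rng):
        X = rng.normal(size=(30, 1))
        y = (rng.random(30) < 0.2).astype(int)
        y[:2] = 1
        summ = bootstrap_evaluate(X, y, ModelSpec("Tree", {"max_depth": [2]}), B=5, seed=1)
        assert set(summ.skipped) == set(summ.means)
        assert all(v >= 0 for v in summ.skipped.values())


class TestKMeansElbow:
    def test_one_cluster_closed_form(self, rng):
        X = rng.normal(size=(30, 2))
        inertia, _ = kmeans_elbow(X, k_max=3, seed=0)
        total_ss = ((X - X.mean(axis=0)) ** 2).sum()
        assert inertia[1] == pytest.approx(total_ss)

    def test_each_point_own_center_gives_zero(self, rng):
        X = rng.normal(size=(8, 2))
        inertia, _ = kmeans_elbow(X, k_max=8, seed=0)
        assert inertia[8] == pytest.approx(0.0, abs=1e-9)

    def test_inertia_non_increasing(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 3))
            inertia, labels = kmeans_elbow(X, k_max=10, seed=seed)
            assert (np.diff(inertia.to_numpy()) <= 1e-9).all()
            assert len(np.unique(labels)) == 3
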