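import math

import numpy as np
import pytest

from rnaloc.io import LocalizationTarget
from rnaloc.metrics import (
    ConfusionCounts,
    auc_curves,
    best_threshold_metrics,
    classification_metrics,
    confusion_by_compartment,
    cross_validate,
    make_folds,
    pearson_by_location,
    spearman_per_mrna,
)
from rnaloc.model import FeatureMatrix, ModelConfig


class TestMakeFolds:
    def test_partition_property(self):
        ids = [f"m{i}" for i in range(100)]
        plan = make_folds(ids, n_folds=10, n_repeats=3, seed=0)
        for rep in range(3):
            sizes = [len(plan.fold_ids(rep, f)[1]) for f in range(10)]
            assert sizes == [10] * 10
            all_test = [m for f in range(10) for m in plan.fold_ids(rep, f)[1]]
            assert sorted(all_test) == sorted(ids)

    def test_same_seed_identical_plan(self):
        ids = [f"m{i}" for i in range(30)]
        a = make_folds(ids, n_folds=5, n_repeats=2, seed=9)
        b = make_folds(ids, n_folds=5, n_repeats=2, seed=9)
        assert a.assignments == b.assignments

    def test_stratification_bound(self):
        ids = [f"m{i}" for i in range(100)]
        labels = [0] * 80 + [1] * 20
        plan = make_folds(ids, labels, n_folds=10, n_repeats=2, seed=1, stratified=True)
        for rep in range(2):
            for f in range(10):
                _, test = plan.fold_ids(rep, f)
                n_minor = sum(labels[ids.index(m)] == 1 for m in test)
                assert abs(n_minor - 2) <= 1

    def test_small_class_warns(self):
        ids = [f"m{i}" for i in range(20)]
        labels = [0] * 17 + [1] * 3
        with pytest.warns(UserWarning, match="fewer members"):
            make_folds(ids, labels, n_folds=5, n_repeats=1, seed=0, stratified=True)


class TestPearson:
    def test_perfect_and_inverse(self, rng):
        obs = rng.random((20, 4))
        np.testing.assert_allclose(pearson_by_location(obs, obs), 1.0, atol=1e-12)
        np.testing.assert_allclose(pearson_by_location(-obs + 2, obs), -1.0, atol=1e-12)

    def test_matches_textbook_formula(self, rng):
        pred, obs = rng.random((50, 4)), rng.random((50, 4))
        got = pearson_by_location(pred, obs)
        for j in range(4):
            x, y = pred[:, j], obs[:, j]
            expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            assert abs(got[j] - expected) < 1e-12

    def test_zero_variance_column_missing_with_warning(self, rng):
        pred = rng.random((10, 2))
        obs = rng.random((10, 2))
        pred[:, 1] = 0.5
        with pytest.warns(UserWarning, match="zero variance"):
            out = pearson_by_location(pred, obs)
        assert np.isfinite(out[0]) and np.isnan(out[1])


def brute_force_average_ranks(row):
    """Independent oracle: average ranks with tie handling by enumeration."""
    order = sorted(range(len(row)), key=lambda i: row[i])
    ranks = [0.0] * len(row)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and row[order[j + 1]] == row[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


class TestSpearman:
    def test_same_order_is_one(self):
        pred = np.array([[0.4, 0.3, 0.2, 0.1]])
        obs = np.array([[0.7, 0.2, 0.06, 0.04]])
        rho, n_perfect = spearman_per_mrna(np.vstack([pred, pred]), np.vstack([obs, obs]))
        np.testing.assert_allclose(rho, 1.0)
        assert n_perfect == 2

    def test_reversed_order_is_minus_one(self):
        pred = np.array([[0.4, 0.3, 0.2, 0.1], [0.4, 0.3, 0.2, 0.1]])
        obs = pred[:, ::-1]
        rho, n_perfect = spearman_per_mrna(pred, obs)
        np.testing.assert_allclose(rho, -1.0)
        assert n_perfect == 0

    def test_ties_match_rank_oracle(self, rng):
        pred = rng.integers(0, 3, size=(30, 5)).astype(float)  # many ties
        obs = rng.integers(0, 3, size=(30, 5)).astype(float)
        rho, _ = spearman_per_mrna(pred, obs)
        for i in range(30):
            if np.isnan(rho[i]):
                continue
            rp = np.array(brute_force_average_ranks(pred[i]))
            ro = np.array(brute_force_average_ranks(obs[i]))
            expected = np.corrcoef(rp, ro)[0, 1]
            assert abs(rho[i] - expected) < 1e-12

    def test_constant_row_is_missing(self):
        rho, n_perfect = spearman_per_mrna(np.array([[0.25, 0.25, 0.25, 0.25]]),
                                           np.array([[0.4, 0.3, 0.2, 0.1]]))
        assert np.isnan(rho[0]) and n_perfect == 0


class TestClassificationMetrics:
    def test_perfect_predictor(self):
        m = classification_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_zero_rule(self):
        with pytest.warns(UserWarning):
            m = classification_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert m["precision"] == 0.0 and m["recall"] == 0.0

    def test_hand_evaluated_formulas(self):
        m = classification_metrics(ConfusionCounts(tp=4, tn=3, fp=2, fn=1))
        assert m["precision"] == 4 / 6
        assert m["recall"] == 4 / 5
        assert abs(m["f_score"] - 2 * (4 / 6) * (4 / 5) / (4 / 6 + 4 / 5)) < 1e-12
        assert m["acc"] == 7 / 10
        expected_mcc = (4 * 3 - 2 * 1) / math.sqrt(6 * 5 * 5 * 4)
        assert abs(m["mcc"] - expected_mcc) < 1e-12

    def test_mcc_symmetric_under_class_swap(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 20, size=4)
            a = classification_metrics(ConfusionCounts(tp, tn, fp, fn))["mcc"]
            b = classification_metrics(ConfusionCounts(tn, tp, fn, fp))["mcc"]
            assert abs(a - b) < 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_one_vs_rest_tables_sum_to_n(self):
        true = np.array([0, 0, 1, 2, 2, 2])
        pred = np.array([0, 1, 1, 2, 0, 2])
        tables = confusion_by_compartment(true, pred, 3)
        assert all(t.total == 6 for t in tables)
        assert tables[2].tp == 2 and tables[2].fn == 1


class TestAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        labels = np.array([[1], [1], [0], [0]])
        roc, pr = auc_curves(scores, labels)
        assert roc[0] == 1.0 and pr[0] == 1.0

    def test_random_scores_near_half(self, rng):
        n = 2000
        scores = rng.random((n, 1))
        labels = (rng.random((n, 1)) < 0.5).astype(int)
        roc, _ = auc_curves(scores, labels)
        assert abs(roc[0] - 0.5) < 0.05

    def test_equals_pairwise_concordance(self, rng):
        """Mann-Whitney identity on a toy set, by exhaustive pair counting."""
        scores = rng.random((10, 1))
        labels = np.array([[1], [0], [1], [0], [0], [1], [0], [1], [0], [0]])
        pos = scores[labels[:, 0] == 1, 0]
        neg = scores[labels[:, 0] == 0, 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = conc / (len(pos) * len(neg))
        roc, _ = auc_curves(scores, labels)
        assert abs(roc[0] - expected) < 1e-12

    def test_single_class_compartment_zero_with_warning(self):
        scores = np.array([[0.2, 0.8], [0.3, 0.7]])
        labels = np.array([[0, 1], [0, 1]])
        with pytest.warns(UserWarning, match="single class"):
            roc, pr = auc_curves(scores, labels)
        assert roc[0] == 0.0 and pr[0] == 0.0


class TestBestThreshold:
    def test_perfect_separation_f1(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        labels = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        t, m = best_threshold_metrics(scores, labels, [0.5])
        assert m["f_score"] == 1.0

    def test_single_value_grid_is_fixed_threshold(self, rng):
        scores = rng.random((20, 3))
        labels = np.eye(3)[rng.integers(3, size=20)]
        t, _ = best_threshold_metrics(scores, labels, [0.4])
        assert t == 0.4

    def test_matches_exhaustive_scan(self, rng):
        scores = rng.random((20, 3))
        labels = np.eye(3)[rng.integers(3, size=20)]
        grid = list(np.round(np.arange(0.05, 0.96, 0.05), 2))
        t_best, m_best = best_threshold_metrics(scores, labels, grid)
        brute = []
        for t in grid:
            _, m = best_threshold_metrics(scores, labels, [t])
            brute.append((m["f_score"], -t))
        assert m_best["f_score"] == max(brute)[0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            best_threshold_metrics(np.zeros((2, 2)), np.eye(2), [])


class TestCrossValidate:
    def _corpus(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 6)) * 0.2
        X[np.arange(n), labels] += 2.0
        ids = [f"m{i}" for i in range(n)]
        Y = LocalizationTarget("discrete", ["a", "b"], ids, labels.astype(np.int64))
        return FeatureMatrix(ids=ids, values=X), Y, labels

    def test_deterministic_report(self):
        X, Y, labels = self._corpus()
        cfg = ModelConfig(hidden_units=8, epochs=15, batch_size=32, seed=5)
        plan = make_folds(X.ids, labels, n_folds=4, n_repeats=1, seed=2, stratified=True)
        r1 = cross_validate(X, Y, cfg, plan)
        r2 = cross_validate(X, Y, cfg, plan)
        assert r1.overall == r2.overall

    def test_learnable_corpus_high_accuracy(self):
        X, Y, labels = self._corpus(n=120)
        cfg = ModelConfig(hidden_units=8, epochs=40, batch_size=32, seed=5)
        plan = make_folds(X.ids, labels, n_folds=4, n_repeats=1, seed=2, stratified=True)
        report = cross_validate(X, Y, cfg, plan)
        assert report.overall["overall_acc"] >= 0.9

    def test_permuted_labels_near_chance(self):
        X, Y, labels = self._corpus(n=120, seed=1)
        rng = np.random.default_rng(0)
        permuted = rng.permutation(Y.values)
        Y_null = LocalizationTarget("discrete", Y.compartments, Y.ids, permuted)
        cfg = ModelConfig(hidden_units=8, epochs=30, batch_size=32, seed=5)
        plan = make_folds(X.ids, permuted, n_folds=4, n_repeats=1, seed=2, stratified=True)
        report = cross_validate(X, Y_null, cfg, plan)
        assert abs(report.overall["overall_acc"] - 0.5) <= 0.15

    def test_continuous_mode_reports_correlations(self):
        rng = np.random.default_rng(4)
        n = 80
        ids = [f"m{i}" for i in range(n)]
        X = rng.normal(size=(n, 5))
        raw = np.abs(X[:, :4]) + 0.1
        target = raw / raw.sum(axis=1, keepdims=True)
        Y = LocalizationTarget("continuous", list("abcd"), ids, target)
        cfg = ModelConfig(hidden_units=8, epochs=20, batch_size=32, seed=3)
        plan = make_folds(ids, n_folds=4, n_repeats=2, seed=1)
        report = cross_validate(FeatureMatrix(ids=ids, values=X), Y, cfg, plan)
        assert set(report.overall) >= {"mean_pearson", "mean_spearman",
                                       "n_spearman_perfect"}
        assert "pearson" in report.per_compartment["a"]
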