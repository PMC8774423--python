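"""Standardization, stacking ensemble, k-medoids, protocols and metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nucleiclust.classify import (
    ClassificationError,
    compute_metrics,
    confusion_matrix,
    fit_stacked_ensemble,
    five_fold_evaluate,
    kmedoids_classify,
    map_clusters_to_labels,
    standardize,
)
from nucleiclust.pipeline import _StackedFactory


class TestStandardize:
    def test_direct_evaluation(self):
        scaled, params = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert params.means[0] == 2.0
        assert params.stds[0] == pytest.approx(np.sqrt(2 / 3))
        assert scaled.ravel() == pytest.approx([-1.22474487, 0.0, 1.22474487])

    def test_constant_column_maps_to_zero(self):
        scaled, _ = standardize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(scaled[:, 0] == 0)

    def test_scaled_columns_are_zero_mean_unit_std(self, rng):
        x = rng.normal(10, 3, (50, 4))
        scaled, _ = standardize(x)
        assert np.allclose(scaled.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(scaled.std(axis=0), 1, atol=1e-12)

    def test_params_reusable_on_new_data(self, rng):
        train = rng.normal(0, 1, (30, 2))
        _, params = standardize(train)
        test = rng.normal(0, 1, (10, 2))
        scaled, _ = standardize(test, params)
        assert np.allclose(scaled, (test - params.means) / params.stds)

    def test_empty_table_rejected(self):
        with pytest.raises(ClassificationError):
            standardize(np.empty((0, 3)))


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(3)
    x = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(5, 1, (100, 4))])
    y = np.repeat([0, 1], 100)
    return x, y


class TestStackedEnsemble:
    def test_separable_two_class_problem_solved(self, separable_data):
        x, y = separable_data
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(x))
        train, test = idx[:160], idx[160:]
        model = fit_stacked_ensemble(x[train], y[train], seed=0)
        assert np.mean(model.predict(x[test]) == y[test]) >= 0.95

    def test_meta_feature_width_is_four_times_n_classes(self, separable_data):
        x, y = separable_data
        model = fit_stacked_ensemble(x, y, seed=0)
        assert model.meta_features_.shape == (len(x), 4 * 2)

    def test_same_seed_identical_predictions(self, separable_data):
        x, y = separable_data
        a = fit_stacked_ensemble(x, y, seed=5).predict(x)
        b = fit_stacked_ensemble(x, y, seed=5).predict(x)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ClassificationError):
            fit_stacked_ensemble(np.zeros((10, 2)), np.zeros(10), seed=0)

    def test_beats_or_ties_worst_base_learner(self, separable_data):
        # sanity property at strong separation: the stack should not trail
        # its weakest component
        x, y = separable_data
        rng = np.random.default_rng(1)
        idx = rng.permutation(len(x))
        train, test = idx[:160], idx[160:]
        model = fit_stacked_ensemble(x[train], y[train], seed=1)
        stack_acc = np.mean(model.predict(x[test]) == y[test])
        base_accs = [
            np.mean(m.predict(x[test]) == y[test]) for _, m in model.base_models
        ]
        assert stack_acc >= min(base_accs)


class TestFiveFold:
    def test_perfect_classifier_scores_100_everywhere(self):
        class Perfect:
            def fit(self, x, y):
                return self

            def predict(self, x):
                return (x[:, 0] > 0).astype(int)

        x = np.vstack([-np.ones((50, 1)), np.ones((50, 1))]) * 3.0
        x = x + np.random.default_rng(0).normal(0, 0.1, x.shape)
        y = np.repeat([0, 1], 50)
        table = five_fold_evaluate(lambda seed: Perfect(), x, y, seed=0)
        assert np.allclose(table.to_numpy(), 100.0)

    def test_average_row_is_mean_of_split_rows(self, separable_data):
        x, y = separable_data
        table = five_fold_evaluate(lambda seed: _StackedFactory(seed), x, y, seed=0)
        splits = table.iloc[:-1]
        assert np.allclose(table.loc["Average Split"], splits.mean())
        assert len(table) == 6

    def test_cv_mode_partitions_data(self, separable_data):
        x, y = separable_data

        class Recorder:
            seen = []

            def fit(self, xx, yy):
                return self

            def predict(self, xx):
                Recorder.seen.append(len(xx))
                return np.zeros(len(xx), dtype=int)

        Recorder.seen = []
        five_fold_evaluate(lambda seed: Recorder(), x, y, seed=0, mode="cv")
        assert sum(Recorder.seen) == len(x)  # test folds cover the data once

    def test_small_class_rejected(self):
        x = np.zeros((6, 2))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ClassificationError):
            five_fold_evaluate(lambda seed: None, x, y, n_splits=5)


class TestKMedoids:
    def test_k_equals_n_is_zero_cost(self, rng):
        x = rng.normal(0, 1, (8, 3))
        assign = kmedoids_classify(x, k=8)
        assert len(np.unique(assign)) == 8

    def test_two_blobs_match_exhaustive_medoid_search(self, rng):
        x = np.vstack([rng.normal(0, 0.5, (12, 2)), rng.normal(8, 0.5, (12, 2))])
        assign = kmedoids_classify(x, k=2)
        blob = np.repeat([0, 1], 12)
        acc = max(np.mean(assign == blob), np.mean(assign != blob))
        assert acc == 1.0
        # cost equals brute-force minimum over all medoid pairs
        from scipy.spatial.distance import cdist

        d = cdist(x, x)
        pam_cost = min(
            d[:, list(pair)].min(axis=1).sum() for pair in itertools.combinations(range(24), 2)
        )
        medoid_cost = None
        for pair in itertools.combinations(range(24), 2):
            c = d[:, list(pair)].min(axis=1).sum()
            if medoid_cost is None or c < medoid_cost:
                medoid_cost = c
        got_cost = 0.0
        for cluster in np.unique(assign):
            members = np.where(assign == cluster)[0]
            got_cost += min(d[np.ix_(members, [m])].sum() for m in members)
        assert got_cost == pytest.approx(pam_cost) == pytest.approx(medoid_cost)

    def test_invalid_k_rejected(self):
        with pytest.raises(ClassificationError):
            kmedoids_classify(np.zeros((5, 2)), k=6)


class TestClusterLabelMapping:
    def test_relabeled_assignments_score_perfectly(self):
        y = np.array(["A", "B", "A", "B", "B"])
        assign = np.array([1, 0, 1, 0, 0])
        mapping = map_clusters_to_labels(assign, y)
        assert all(mapping[a] == t for a, t in zip(assign, y))

    def test_picks_better_of_two_permutations(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        assign = np.array([0, 0, 1, 1, 1, 1])  # identity mapping: 5/6 correct
        mapping = map_clusters_to_labels(assign, y)
        hits = sum(mapping[a] == t for a, t in zip(assign, y))
        flipped = sum({0: 1, 1: 0}[a] == t for a, t in zip(assign, y))
        assert hits == max(hits, flipped) == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClassificationError):
            map_clusters_to_labels([0, 1], [0, 1, 2])


class TestMetrics:
    def test_worked_binary_example(self):
        # TP=9, FN=1, FP=2, TN=8
        cm = np.array([[8, 2], [1, 9]])
        m = compute_metrics(cm)
        assert m.accuracy == pytest.approx(85.0)
        assert m.precision == pytest.approx(81.82, abs=0.005)
        assert m.recall == pytest.approx(90.0)
        assert m.f1 == pytest.approx(85.71, abs=0.005)

    def test_diagonal_matrix_is_perfect(self):
        m = compute_metrics(np.diag([5, 7, 9]))
        assert m.accuracy == m.precision == m.recall == m.f1 == 100.0

    def test_all_wrong_matrix_is_zero_accuracy(self):
        m = compute_metrics(np.array([[0, 4], [6, 0]]))
        assert m.accuracy == 0.0
        assert "precision[1]" in m.undefined or m.precision == 0.0

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(20):
            cm = rng.integers(1, 30, (2, 2))
            m = compute_metrics(cm)
            assert min(m.precision, m.recall) - 1e-9 <= m.f1 <= max(m.precision, m.recall) + 1e-9

    def test_confusion_matrix_layout(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1])
        assert cm.loc[0, 1] == 1  # true 0 predicted 1
        assert cm.to_numpy().sum() == 4
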