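"""Classification: pipeline fitting, nested CV, metrics, DeLong AUC."""
import numpy as np
import pytest

from ddfa_hrv import CVConfig, TaskSpec, delong_auc, fit_model, metrics, nested_cv

BINARY = TaskSpec("binary", ("pos", "neg"), positive_class="pos")
MULTI = TaskSpec("multiclass", ("healthy", "chf", "af"))

SMALL_GRID = {
    "pca__n_components": [3],
    "xgb__n_estimators": [50],
    "xgb__max_depth": [2],
    "xgb__learning_rate": [0.3],
}


def _blobs(n_per_class, centers, spread=0.3, seed=0, n_features=6):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, center in enumerate(centers):
        x = center + rng.normal(0.0, spread, (n_per_class, n_features))
        xs.append(x)
        ys.append(np.full(n_per_class, label))
    return np.vstack(xs), np.concatenate(ys)


class TestFitModel:
    def test_separable_classes_fit_perfectly(self):
        x, y = _blobs(20, [0.0, 10.0])
        model = fit_model(x, y, {"pca__n_components": 3}, seed=0)
        assert (model.predict(x) == y).mean() == 1.0

    def test_same_seed_reproduces_predictions(self):
        x, y = _blobs(20, [0.0, 2.0], spread=1.5)
        a = fit_model(x, y, seed=3).predict(x)
        b = fit_model(x, y, seed=3).predict(x)
        np.testing.assert_array_equal(a, b)

    def test_excess_pca_components_capped_with_warning(self):
        x, y = _blobs(5, [0.0, 5.0])
        with pytest.warns(UserWarning, match="capped"):
            model = fit_model(x, y, {"pca__n_components": 50}, seed=0)
        assert model.named_steps["pca"].n_components_ <= min(x.shape)

    def test_single_class_training_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="single class"):
            fit_model(x, np.zeros(10, dtype=int))


class TestMetrics:
    def test_binary_sensitivity_and_specificity(self):
        confusion = np.array([[8, 2], [1, 9]])  # rows: true pos, true neg
        sens, spec, bacc = metrics(confusion, BINARY)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)
        assert bacc == pytest.approx(0.85)

    def test_identity_confusion_is_perfect(self):
        sens, spec, bacc = metrics(np.diag([10, 15]), BINARY)
        assert sens == spec == bacc == 1.0

    def test_multiclass_balanced_accuracy_is_mean_recall(self):
        confusion = np.array([[1, 1, 0], [0, 3, 1], [0, 0, 4]])
        # recalls 0.5, 0.75, 1.0
        _, _, bacc = metrics(confusion, MULTI)
        assert bacc == pytest.approx(0.75)

    def test_empty_class_row_excluded_with_warning(self):
        confusion = np.array([[5, 0, 0], [0, 0, 0], [0, 0, 5]])
        with pytest.warns(UserWarning, match="chf"):
            _, _, bacc = metrics(confusion, MULTI)
        assert bacc == pytest.approx(1.0)


class TestDeLong:
    def test_perfect_separation(self):
        result = delong_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert result.auc == 1.0

    def test_worked_four_score_case(self):
        # 3 of 4 (pos, neg) pairs concordant
        result = delong_auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0])
        assert result.auc == pytest.approx(0.75)
        assert result.n_pos == result.n_neg == 2

    def test_all_ties_give_half(self):
        result = delong_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert result.auc == pytest.approx(0.5)

    def test_ci_brackets_the_estimate(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.r_[np.ones(40, int), np.zeros(40, int)]
        result = delong_auc(scores, labels)
        assert result.ci95[0] <= result.auc <= result.ci95[1]
        assert 0.0 <= result.ci95[0] and result.ci95[1] <= 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_pairwise_auc(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 12, 2)
        pos = np.round(rng.normal(0.6, 0.3, m), 1)  # rounding forces ties
        neg = np.round(rng.normal(0.4, 0.3, n), 1)
        brute = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        result = delong_auc(
            np.concatenate([pos, neg]), np.r_[np.ones(m, int), np.zeros(n, int)]
        )
        assert result.auc == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_auc([0.1, 0.2], [1, 1])


class TestNestedCV:
    def test_separated_cohort_scores_perfectly(self):
        x, y = _blobs(16, [0.0, 10.0], seed=1)
        labels = np.where(y == 0, "pos", "neg")
        report = nested_cv(
            x, labels, BINARY,
            CVConfig(outer_folds=4, inner_folds=3, param_grid=SMALL_GRID, seed=0),
        )
        summary = report.to_dict()
        assert summary["mean_sensitivity"] == 1.0
        assert summary["mean_specificity"] == 1.0

    def test_outer_folds_are_half_splits_with_disjoint_train_test(self):
        x, y = _blobs(15, [0.0, 8.0], seed=2)
        labels = np.where(y == 0, "pos", "neg")
        report = nested_cv(
            x, labels, BINARY,
            CVConfig(outer_folds=5, inner_folds=3, param_grid=SMALL_GRID, seed=1),
        )
        for fold in report.per_fold:
            assert set(fold.train_indices).isdisjoint(fold.test_indices)
            assert len(fold.train_indices) + len(fold.test_indices) == 30
            assert abs(len(fold.test_indices) - 15) <= 1

    def test_confusion_percent_rows_sum_to_100(self):
        x, y = _blobs(12, [0.0, 4.0, 8.0], seed=3)
        labels = np.array(["healthy", "chf", "af"])[y]
        report = nested_cv(
            x, labels, MULTI,
            CVConfig(outer_folds=3, inner_folds=3, param_grid=SMALL_GRID, seed=2),
        )
        np.testing.assert_allclose(report.confusion_percent.sum(axis=1), 100.0)

    def test_fold_results_are_reproducible_from_their_training_half(self):
        x, y = _blobs(12, [0.0, 6.0], seed=4)
        labels = np.where(y == 0, "pos", "neg")
        cv = CVConfig(outer_folds=2, inner_folds=3, param_grid=SMALL_GRID, seed=5)
        report = nested_cv(x, labels, BINARY, cv)
        fold = report.per_fold[0]
        codes = np.where(labels == "pos", 0, 1)
        model = fit_model(x[fold.train_indices], codes[fold.train_indices],
                          fold.chosen_params, seed=cv.seed)
        pred = model.predict(x[fold.test_indices])
        rebuilt = np.zeros((2, 2), int)
        np.add.at(rebuilt, (codes[fold.test_indices], pred), 1)
        np.testing.assert_array_equal(rebuilt, fold.confusion)

    def test_resize_grid_requires_feature_builder(self):
        x, y = _blobs(10, [0.0, 5.0])
        grid = dict(SMALL_GRID, resize=[(8, 8)])
        with pytest.raises(ValueError, match="feature_builder"):
            nested_cv(x, np.where(y == 0, "pos", "neg"), BINARY,
                      CVConfig(outer_folds=2, inner_folds=3, param_grid=grid))

    def test_small_class_rejected_by_name(self):
        x, y = _blobs(4, [0.0, 5.0])
        with pytest.raises(ValueError, match="pos"):
            nested_cv(x, np.where(y == 0, "pos", "neg"), BINARY,
                      CVConfig(outer_folds=2, inner_folds=10))


def test_task_validation():
    with pytest.raises(ValueError):
        TaskSpec("binary", ("a", "b"))  # no positive class
    with pytest.raises(ValueError):
        TaskSpec("binary", ("a", "b", "c"), positive_class="a")
    with pytest.raises(ValueError):
        CVConfig(test_fraction=1.5)
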