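import numpy as np
import pytest
from sklearn.linear_model import LassoLars

from homnet import (
    ConfusionCounts,
    FeatureTable,
    HyperGrid,
    classification_metrics,
    lasso_select,
    lower_triangle_index,
    nested_cv,
    selection_frequency,
    train_svm,
    ttest_filter,
    vectorize_lower,
)
from homnet.data_io import ValidationError
from homnet.ml_pipeline import (
    SelectionRecord,
    _lasso_coef,
    fit_fold,
    lambda_max,
)

SMALL_GRID = HyperGrid(
    p_thresholds=(0.05, 0.5), lambda_fracs=(0.05, 0.3, 1.0), svm_costs=(1.0,)
)


def _gaussian_table(rng, n_per_class=10, p=12, n_informative=3, shift=2.0, tag="t"):
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    x = rng.standard_normal((2 * n_per_class, p))
    x[:, :n_informative] += shift * y[:, None] / 2.0
    r = int(np.ceil((1 + np.sqrt(1 + 8 * p)) / 2))
    ids = lower_triangle_index(r)[:p]
    return FeatureTable(X=x, y=y, feature_ids=ids, network_tag=tag)


class TestVectorize:
    def test_smallest_case_ordering(self):
        # 1-based report pairs: (2,1), (3,1), (3,2)
        assert lower_triangle_index(3) == [(1, 0), (2, 0), (2, 1)]
        net = np.array([[1.0, 0.2, 0.3], [0.2, 1.0, 0.4], [0.3, 0.4, 1.0]])
        assert vectorize_lower(net).tolist() == [0.2, 0.3, 0.4]

    def test_full_atlas_dimensionality(self):
        # 116 regions -> 116*115/2 = 6670 edge features
        assert len(lower_triangle_index(116)) == 6670

    def test_zero_network_maps_to_zero_vector(self):
        assert np.all(vectorize_lower(np.eye(4)) == 0.0)

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValidationError, match="asymmetric"):
            vectorize_lower(a)

    def test_inverse_mapping_recoverable(self, rng):
        a = rng.standard_normal((5, 5))
        a = (a + a.T) / 2
        vec = vectorize_lower(a)
        for k, (i, j) in enumerate(lower_triangle_index(5)):
            assert vec[k] == a[i, j]


class TestTtestFilter:
    def test_threshold_one_keeps_all_finite(self, rng):
        x = rng.standard_normal((20, 8))
        y = np.array([1] * 10 + [-1] * 10)
        assert ttest_filter(x, y, 1.0).all()

    def test_strong_effect_retained(self, rng):
        # class means 0 vs 5, sd 0.1: p vanishes, feature must survive at 0.01
        y = np.array([1] * 20 + [-1] * 20)
        x = rng.standard_normal((40, 3))
        x[:, 1] = 0.1 * rng.standard_normal(40) + np.where(y == 1, 5.0, 0.0)
        mask = ttest_filter(x, y, 0.01)
        assert mask[1]

    def test_null_type_one_error_near_nominal(self, rng):
        # 1000 independent null features at alpha=0.05: retention ~ Binom(1000, .05)
        x = rng.standard_normal((40, 1000))
        y = np.array([1] * 20 + [-1] * 20)
        frac = ttest_filter(x, y, 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_zero_variance_feature_excluded_with_warning(self, rng):
        x = rng.standard_normal((20, 3))
        x[:, 0] = 1.0
        y = np.array([1] * 10 + [-1] * 10)
        with pytest.warns(UserWarning, match="zero-variance"):
            mask = ttest_filter(x, y, 1.0)
        assert not mask[0]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            ttest_filter(rng.standard_normal((10, 3)), np.ones(10, dtype=int), 0.05)


class TestLasso:
    def test_full_shrinkage_above_lambda_max(self, rng):
        x = rng.standard_normal((30, 6))
        x = (x - x.mean(0)) / x.std(0)
        y = np.array([1] * 15 + [-1] * 15)
        assert not lasso_select(x, y, lambda_max(x, y) * 1.001).any()

    def test_lambda_zero_is_least_squares(self, rng):
        x = rng.standard_normal((30, 6))
        y = np.array([1] * 15 + [-1] * 15).astype(float)
        assert lasso_select(x, y, 0.0).all()
        coef = _lasso_coef(x, y, 0.0)
        want, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert np.allclose(coef, want, atol=1e-10)

    def test_matches_lars_oracle(self, rng):
        x = rng.standard_normal((30, 6))
        x = (x - x.mean(0)) / x.std(0)
        y = np.array([1] * 15 + [-1] * 15).astype(float)
        lam = 0.15 * lambda_max(x, y)
        coef = _lasso_coef(x, y, lam)
        # LARS solves the same objective with alpha = lam / n by a different path
        oracle = LassoLars(alpha=lam / len(y), fit_intercept=False)
        oracle.fit(x, y)
        assert np.max(np.abs(coef - oracle.coef_)) <= 1e-6

    def test_support_size_nonincreasing_on_grid(self, rng):
        x = rng.standard_normal((40, 10))
        x = (x - x.mean(0)) / x.std(0)
        y = np.array([1] * 20 + [-1] * 20)
        lmax = lambda_max(x, y)
        sizes = [
            lasso_select(x, y, f * lmax).sum() for f in HyperGrid().lambda_fracs
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            lasso_select(np.array([[np.nan, 1.0]]), np.array([1.0]), 0.1)


class TestSvm:
    def test_separable_points_perfect(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        model = train_svm(x, y, 1.0)
        assert np.array_equal(model.predict(x), y)

    def test_xor_not_linearly_separable(self):
        x = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([1, 1, -1, -1])
        model = train_svm(x, y, 10.0)
        assert np.mean(model.predict(x) == y) <= 0.75

    def test_gaussian_task_beats_chance(self, rng):
        x = rng.standard_normal((200, 4))
        y = np.where(x[:, 0] + 0.5 * rng.standard_normal(200) > 0, 1, -1)
        model = train_svm(x[:100], y[:100], 1.0)
        assert np.mean(model.predict(x[100:]) == y[100:]) > 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_svm(np.zeros((3, 2)), np.ones(3, dtype=int), 1.0)


class TestMetrics:
    def test_perfect_classification(self):
        m = classification_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (m.acc, m.tpr, m.tnr, m.f1) == (100.0, 100.0, 100.0, 100.0)

    def test_hand_computed_values(self):
        m = classification_metrics(ConfusionCounts(tp=8, fn=2, tn=7, fp=3))
        assert m.acc == pytest.approx(75.0)
        assert m.tpr == pytest.approx(80.0)
        assert m.tnr == pytest.approx(70.0)
        assert m.f1 == pytest.approx(100 * 16 / 21, abs=0.005)  # 76.19

    def test_undefined_metric_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="TPR undefined"):
            m = classification_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m.tpr)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_pooled_equals_mean_for_equal_folds(self):
        folds = [ConfusionCounts(3, 4, 2, 1), ConfusionCounts(4, 3, 1, 2)]
        pooled = ConfusionCounts(7, 7, 3, 3)
        mean_acc = np.mean([classification_metrics(c).acc for c in folds])
        assert classification_metrics(pooled).acc == pytest.approx(mean_acc)


class TestNestedCv:
    def test_same_seed_reproduces_everything(self, rng):
        table = _gaussian_table(rng)
        a = nested_cv(table, repetitions=2, seed=5, grid=SMALL_GRID)
        b = nested_cv(table, repetitions=2, seed=5, grid=SMALL_GRID)
        assert np.array_equal(a.oof_predictions, b.oof_predictions)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.metrics == b.metrics
        assert all(
            np.array_equal(ra.mask, rb.mask) and ra.lam == rb.lam
            for ra, rb in zip(a.records, b.records)
        )

    def test_every_subject_predicted_once_per_repetition(self, rng):
        table = _gaussian_table(rng)
        res = nested_cv(table, repetitions=2, seed=5, grid=SMALL_GRID)
        assert res.oof_predictions.shape == (2, 20)
        assert np.all(np.isin(res.oof_predictions, (-1, 1)))
        assert np.all(res.fold_assignment >= 0)
        assert len(res.fold_counts) == 10  # 2 repetitions x 5 folds

    def test_separable_effect_recovered(self, rng):
        table = _gaussian_table(rng, shift=4.0)
        res = nested_cv(table, repetitions=2, seed=5, grid=SMALL_GRID)
        assert res.metrics.acc > 75.0

    def test_no_leakage_from_test_fold(self, rng):
        # corrupting the held-out labels must not change training-fold tuning,
        # selection or predictions
        table = _gaussian_table(rng)
        idx = np.arange(20)
        train_idx, test_idx = idx[:16], idx[16:]
        rec_a, pred_a, _ = fit_fold(
            table.X, table.y, train_idx, test_idx, SMALL_GRID, inner_seed=7
        )
        y_corrupt = table.y.copy()
        y_corrupt[test_idx] *= -1
        rec_b, pred_b, _ = fit_fold(
            table.X, y_corrupt, train_idx, test_idx, SMALL_GRID, inner_seed=7
        )
        assert np.array_equal(rec_a.mask, rec_b.mask)
        assert (rec_a.p_threshold, rec_a.lam, rec_a.svm_cost) == (
            rec_b.p_threshold, rec_b.lam, rec_b.svm_cost,
        )
        assert np.array_equal(pred_a, pred_b)

    def test_too_few_subjects_rejected(self, rng):
        table = _gaussian_table(rng, n_per_class=4)
        with pytest.raises(ValidationError):
            nested_cv(table, repetitions=1, seed=0, grid=SMALL_GRID)


class TestSelectionFrequency:
    def _records(self, picks, total=50, p=4, feature=0):
        recs = []
        for k in range(total):
            mask = np.zeros(p, dtype=bool)
            if k < picks:
                mask[feature] = True
            recs.append(
                SelectionRecord(
                    repetition=k // 5, fold=k % 5, mask=mask,
                    p_threshold=0.05, lambda_frac=0.1, lam=1.0, svm_cost=1.0,
                )
            )
        return recs

    def test_worked_example_49_of_50(self):
        freq = selection_frequency(self._records(49))
        assert freq[0] == pytest.approx(0.98)

    def test_always_and_never_selected(self):
        freq = selection_frequency(self._records(50))
        assert freq[0] == 1.0
        assert freq[1] == 0.0

    def test_inconsistent_dimensions_rejected(self):
        recs = self._records(5, total=5, p=4) + self._records(5, total=5, p=6)
        with pytest.raises(ValidationError, match="inconsistent"):
            selection_frequency(recs)
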