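"""Triangle-kernel Naive Bayes: densities, posteriors, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import specklesense as ss
from specklesense.classify import (FeatureMatrix, concat_features,
                                   cross_validate, default_h_grid, fit_nb,
                                   holdout_eval, predict, predict_batch,
                                   segment_features)
from specklesense.exceptions import ValidationError


def make_features(X, y, groups=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if groups is None:
        groups = np.array([f"r{i}" for i in range(n)], dtype=object)
    return FeatureMatrix(X=X, y=np.asarray(y),
                         groups=np.asarray(groups),
                         offsets=np.zeros(n, dtype=int))


class TestSegmentFeatures:
    @pytest.mark.parametrize("length,window,hop,expected_rows", [
        (10, 10, 1, 1),
        (100, 50, 25, 3),
        (100, 30, 30, 3),
    ])
    def test_row_count(self, length, window, hop, expected_rows, rng):
        trace = rng.normal(size=length)
        fm = segment_features(trace, window, hop, label=1.0)
        assert fm.X.shape == (expected_rows, window)

    def test_window_longer_than_trace_rejected(self, rng):
        with pytest.raises(ValidationError):
            segment_features(rng.normal(size=10), 11, 1, label=1.0)

    def test_row_normalization_flag(self, rng):
        trace = 5.0 * rng.normal(size=100)
        fm = segment_features(trace, 25, 25, label=1.0, normalize_rows=True)
        np.testing.assert_allclose(np.abs(fm.X).max(axis=1), 1.0)

    def test_default_keeps_amplitudes(self, rng):
        trace = 5.0 * rng.normal(size=100)
        fm = segment_features(trace, 25, 25, label=1.0)
        np.testing.assert_array_equal(fm.X[0], trace[:25])

    def test_offsets_are_window_starts(self, rng):
        fm = segment_features(rng.normal(size=100), 40, 20, label=1.0)
        np.testing.assert_array_equal(fm.offsets, [0, 20, 40, 60])

    def test_sorted_abs_transform_is_phase_free(self):
        """Two windows of the same tone at different phases map to nearly
        identical descending order statistics."""
        t = np.arange(200) / 1000.0
        trace = 3.0 * np.sin(2 * np.pi * 140.0 * t)
        fm = segment_features(trace, 100, 57, label=1.0,
                              transform="sorted-abs")
        assert np.all(np.diff(fm.X, axis=1) <= 0)          # descending
        assert fm.X.max() == pytest.approx(3.0, rel=0.01)  # scale kept
        np.testing.assert_allclose(fm.X[0], fm.X[1], atol=0.1)

    def test_unknown_transform_rejected(self, rng):
        with pytest.raises(ValidationError):
            segment_features(rng.normal(size=50), 10, 10, label=1.0,
                             transform="bogus")


class TestFitNB:
    def test_equal_counts_give_equal_priors(self):
        fm = make_features([[0.0], [0.1], [1.0], [1.1]], [0, 0, 1, 1])
        model = fit_nb(fm, bandwidth=1.0)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])
        assert abs(model.priors.sum() - 1.0) < 1e-12

    def test_triangle_kernel_closed_form(self):
        """A single training value v with unit bandwidth puts density
        K(0)/h = 1 at v and 0 at v +/- h."""
        fm = make_features([[3.0], [10.0]], [0, 1])
        model = fit_nb(fm, bandwidth=1.0)
        # feature scale is substituted by the pooled std; force unit scale
        model.feature_scale = np.array([1.0])
        from specklesense.classify import _class_log_likelihood
        at_v = np.exp(_class_log_likelihood(model, np.array([[3.0]]))[0, 0])
        assert at_v == pytest.approx(1.0)
        at_edge = _class_log_likelihood(model, np.array([[4.0]]))[0, 0]
        assert at_edge == -np.inf

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(3)
        fm = make_features(rng.normal(size=(20, 1)), np.zeros(20))
        model = fit_nb(fm, bandwidth=0.7)
        from specklesense.classify import _class_log_likelihood
        grid = np.linspace(-6, 6, 4001)[:, None]
        dens = np.exp(_class_log_likelihood(model, grid)[:, 0])
        integral = np.trapezoid(dens, grid[:, 0])
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_invalid_bandwidth_rejected(self):
        fm = make_features([[0.0], [1.0]], [0, 1])
        with pytest.raises(ValidationError):
            fit_nb(fm, bandwidth=0.0)


class TestPredict:
    def test_hand_posterior(self):
        """Priors (.5, .5); densities p(x|0) = 0.2, p(x|1) = 0.6 at the
        query point give posterior (0.25, 0.75)."""
        # class 0 trains at 0, class 1 at 0.5; query x where the triangle
        # kernels give the target density ratio. With unit h and scale:
        # f0(x) = 1 - |x|, f1(x) = 1 - |x - 0.5|; at x = 0.8: 0.2, 0.7.
        fm = make_features([[0.0], [0.5]], [0, 1])
        model = fit_nb(fm, bandwidth=1.0)
        model.feature_scale = np.array([1.0])
        posterior, label = predict(model, np.array([0.8]))
        np.testing.assert_allclose(posterior, [0.2 / 0.9, 0.7 / 0.9],
                                   rtol=1e-10)
        assert label == 1
        assert posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_training_point_far_from_other_class_wins(self):
        fm = make_features([[0.0], [100.0]], [0, 1])
        model = fit_nb(fm, bandwidth=0.1)
        posterior, label = predict(model, np.array([0.0]))
        assert label == 0
        assert posterior[0] == pytest.approx(1.0)

    def test_fallback_to_priors_outside_all_supports(self):
        fm = make_features([[0.0], [0.0], [0.0], [1.0]], [0, 0, 0, 1])
        model = fit_nb(fm, bandwidth=0.01)
        posterior, label = predict(model, np.array([50.0]))
        np.testing.assert_allclose(posterior, [0.75, 0.25])
        assert label == 0

    def test_log_space_matches_direct_product(self):
        """On a small instance without underflow, the log-space posterior
        equals the directly multiplied Bayes rule."""
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(1, 1, (15, 3))])
        y = np.array([0] * 10 + [1] * 15)
        fm = make_features(X, y)
        model = fit_nb(fm, bandwidth=1.5)
        from specklesense.classify import _class_log_likelihood
        queries = rng.normal(0.5, 1, (20, 3))
        posterior, _ = predict_batch(model, queries)
        loglik = _class_log_likelihood(model, queries)
        lik = np.exp(loglik)
        direct = lik * model.priors[None, :]
        norm = direct.sum(axis=1, keepdims=True)
        ok = norm[:, 0] > 0
        np.testing.assert_allclose(posterior[ok], direct[ok] / norm[ok],
                                   rtol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_posteriors_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 2))
        y = np.array([0] * 6 + [1] * 6)
        model = fit_nb(make_features(X, y), bandwidth=0.8)
        posterior, _ = predict_batch(model, rng.normal(size=(5, 2)))
        np.testing.assert_allclose(posterior.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = fit_nb(make_features([[0.0], [1.0]], [0, 1]), 1.0)
        with pytest.raises(ValidationError):
            predict(model, np.array([0.0, 1.0]))


class TestHoldout:
    def test_separable_classes_are_perfect(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)),
                       rng.normal(10, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        report = holdout_eval(make_features(X, y), bandwidth=0.5, seed=0)
        assert report.overall_accuracy == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        fm = make_features(X, y)
        a = holdout_eval(fm, bandwidth=0.5, seed=3)
        b = holdout_eval(fm, bandwidth=0.5, seed=3)
        assert a.to_json() == b.to_json()

    def test_singleton_class_rejected(self):
        fm = make_features([[0.0], [1.0], [2.0]], [0, 1, 1])
        with pytest.raises(ValidationError):
            holdout_eval(fm, bandwidth=0.5, seed=0)


class TestCrossValidate:
    def _features(self, seed=0, n_per_class=10, classes=3):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(5 * k, 0.5, (n_per_class, 2))
                       for k in range(classes)])
        y = np.repeat(np.arange(classes), n_per_class)
        return make_features(X, y)

    def test_every_row_validated_exactly_once(self):
        fm = self._features()
        report, _ = cross_validate(fm, k=5, seed=1)
        folds = report.fold_assignments
        assert folds.min() >= 0 and folds.max() == 4
        # near-equal fold sizes
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1

    def test_selected_bandwidth_is_grid_optimal(self):
        """Exhaustive re-check: no grid point beats the selected h."""
        fm = self._features(seed=2)
        grid = np.array([0.05, 0.2, 0.8, 2.0])
        report, h = cross_validate(fm, k=5, h_grid=grid, seed=1)

        def cv_accuracy(h_val):
            rep, _ = cross_validate(fm, k=5, h_grid=np.array([h_val]),
                                    seed=1)
            return rep.overall_accuracy

        accs = {h_val: cv_accuracy(h_val) for h_val in grid}
        assert accs[h] == max(accs.values())
        assert report.overall_accuracy == accs[h]

    def test_class_smaller_than_k_rejected(self):
        fm = make_features([[0.0], [1.0], [2.0], [3.0]], [0, 0, 1, 1])
        with pytest.raises(ValidationError):
            cross_validate(fm, k=3, seed=0)

    def test_recording_aggregation_votes_windows(self):
        """With aggregate='recording' the report counts recordings and the
        majority vote of a recording's windows decides its prediction."""
        rng = np.random.default_rng(12)
        parts = []
        for k in range(2):
            for r in range(6):
                trace = rng.normal(3 * k, 0.5, 80)
                parts.append(segment_features(trace, 20, 20, label=k,
                                              recording_id=f"c{k}r{r}"))
        fm = concat_features(parts)
        report, _ = cross_validate(fm, k=3, seed=0, aggregate="recording")
        assert report.confusion.sum() == 12  # recordings, not windows

    def test_unknown_aggregate_rejected(self):
        fm = self._features()
        with pytest.raises(ValidationError):
            cross_validate(fm, k=5, seed=0, aggregate="bogus")

    def test_grouped_windows_stay_in_one_fold(self):
        """All windows of one recording land in the same fold."""
        rng = np.random.default_rng(4)
        parts = []
        for k in range(2):
            for r in range(6):
                trace = rng.normal(5 * k, 1.0, 60)
                parts.append(segment_features(trace, 20, 20, label=k,
                                              recording_id=f"c{k}r{r}"))
        fm = concat_features(parts)
        report, _ = cross_validate(fm, k=3, seed=0)
        for g in np.unique(fm.groups):
            assert np.unique(report.fold_assignments[fm.groups == g]).size == 1


class TestComputeMetrics:
    def test_hand_example(self):
        C = np.array([[8, 2], [1, 9]])
        m = ss.compute_metrics(C)
        assert m["precision"][0] == pytest.approx(8 / 9)
        assert m["recall"][0] == pytest.approx(0.8)
        assert m["f1"][0] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))
        assert m["overall_accuracy"] == pytest.approx(17 / 20)

    def test_diagonal_matrix_is_perfect(self):
        m = ss.compute_metrics(np.diag([5, 3, 7]))
        np.testing.assert_allclose(m["precision"], 1.0)
        np.testing.assert_allclose(m["recall"], 1.0)
        np.testing.assert_allclose(m["f1"], 1.0)
        np.testing.assert_allclose(m["accuracy_pct"], 100.0)
        assert m["overall_accuracy"] == 1.0

    def test_reference_f1_from_printed_precision_recall(self):
        # precision 0.64, recall 1.0 -> F1 = 0.78 at two decimals
        f1 = 2 * 0.64 * 1.0 / (0.64 + 1.0)
        assert round(f1, 2) == 0.78

    def test_f1_zero_when_precision_and_recall_zero(self):
        C = np.array([[0, 5], [0, 5]])
        m = ss.compute_metrics(C)
        assert m["f1"][0] == 0.0

    def test_recall_support_identity(self, rng):
        """sum_k recall_k * support_k = trace(C)."""
        C = rng.integers(0, 20, (6, 6))
        m = ss.compute_metrics(C)
        support = C.sum(axis=1)
        assert np.sum(m["recall"] * support) == pytest.approx(np.trace(C))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            ss.compute_metrics(np.array([[1, 2, 3]]))
        with pytest.raises(ValidationError):
            ss.compute_metrics(np.array([[-1, 0], [0, 1]]))


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        y = np.repeat([0, 1, 2], 10)
        model = fit_nb(make_features(X, y), bandwidth=0.6)
        back = ss.NBModel.from_json(model.to_json())
        q = rng.normal(size=(10, 4))
        p1, l1 = predict_batch(model, q)
        p2, l2 = predict_batch(back, q)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        np.testing.assert_array_equal(l1, l2)
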