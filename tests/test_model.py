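"""Normalization, SMOTE, cost-sensitive boosting, threshold moving, calibration."""

import dataclasses

import numpy as np
import pytest
import xgboost as xgb

from rtfatigue import model as mdl
from rtfatigue.model import BoostParams, ImbalanceConfig


def two_cluster_data(n_neg=170, n_pos=10, d=4, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    Xn = rng.normal(0, 1, (n_neg, d))
    Xp = rng.normal(sep, 1, (n_pos, d))
    X = np.vstack([Xn, Xp])
    y = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    return X, y


class TestNormalizer:
    def test_hand_case(self):
        stats = mdl.fit_normalizer(np.array([[0.0], [2.0]]))
        assert stats.mean[0] == 1.0
        out = mdl.apply_normalizer(stats, np.array([[0.0], [2.0]]))
        assert out.ravel() == pytest.approx([-0.70710678, 0.70710678])

    def test_constant_column_maps_to_zero(self):
        stats = mdl.fit_normalizer(np.array([[5.0, 1.0], [5.0, 3.0]]))
        out = mdl.apply_normalizer(stats, np.array([[5.0, 2.0], [7.0, 2.0]]))
        assert np.all(out[:, 0] == 0.0)

    def test_row_at_training_mean_maps_to_zero_vector(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        stats = mdl.fit_normalizer(X)
        out = mdl.apply_normalizer(stats, X.mean(axis=0, keepdims=True))
        assert out == pytest.approx(np.zeros((1, 3)), abs=1e-12)

    def test_mismatched_ordering_is_hard_error(self):
        stats = mdl.fit_normalizer(np.zeros((3, 2)) + [[1, 2]], ["a", "b"])
        with pytest.raises(ValueError, match="ordering"):
            mdl.apply_normalizer(stats, np.zeros((1, 2)), ["b", "a"])


class TestSMOTE:
    def test_synthetic_count_formula(self):
        X, y = two_cluster_data(n_neg=170, n_pos=10)
        X2, y2 = mdl.smote_oversample(X, y, ImbalanceConfig(smote_ratio=1.0), seed=0)
        assert int((y2 == 1).sum()) - 10 == 160
        assert int((y2 == 0).sum()) == 170

    def test_synthetic_points_are_convex_combinations(self):
        X, y = two_cluster_data(n_neg=60, n_pos=8, seed=1)
        X2, y2 = mdl.smote_oversample(X, y, ImbalanceConfig(smote_ratio=0.5), seed=1)
        minority = X[y == 1]
        synth = X2[len(X) :]
        assert synth.shape[0] == round(0.5 * 60) - 8
        for s in synth:
            resid = []
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    t = float(np.dot(s - minority[i], d) / np.dot(d, d))
                    if -1e-9 <= t <= 1 + 1e-9:
                        resid.append(np.linalg.norm(s - minority[i] - t * d))
            assert min(resid) < 1e-9

    def test_minority_below_two_skips_with_warning(self):
        X, y = two_cluster_data(n_neg=50, n_pos=1)
        with pytest.warns(UserWarning, match="skipped"):
            X2, y2 = mdl.smote_oversample(X, y, ImbalanceConfig(), seed=0)
        assert X2.shape == X.shape

    def test_k_truncated_when_minority_small(self):
        X, y = two_cluster_data(n_neg=50, n_pos=4)
        with pytest.warns(UserWarning, match="truncating"):
            X2, _ = mdl.smote_oversample(X, y, ImbalanceConfig(smote_ratio=0.5), seed=0)
        assert X2.shape[0] > X.shape[0]

    def test_no_oversampling_when_ratio_met(self):
        X, y = two_cluster_data(n_neg=20, n_pos=15)
        X2, y2 = mdl.smote_oversample(X, y, ImbalanceConfig(smote_ratio=0.5), seed=0)
        assert X2.shape == X.shape


class TestFoldPosWeight:
    def test_study_scale_ratio(self):
        y = np.concatenate([np.zeros(2655), np.ones(157)])
        assert mdl.fold_pos_weight(y) == pytest.approx(16.91, abs=0.005)

    @pytest.mark.parametrize("n_neg, n_pos, expected", [(30, 30, 1.0), (90, 30, 3.0)])
    def test_simple_ratios(self, n_neg, n_pos, expected):
        y = np.concatenate([np.zeros(n_neg), np.ones(n_pos)])
        assert mdl.fold_pos_weight(y) == expected

    def test_zero_positives_is_hard_error(self):
        with pytest.raises(ValueError, match="no positive"):
            mdl.fold_pos_weight(np.zeros(10))


class TestBoosting:
    params = BoostParams(n_estimators=40, max_depth=3)

    def test_unit_weight_reproduces_unweighted_training(self):
        X, y = two_cluster_data(seed=3)
        weighted = mdl.train_cost_sensitive_gbt(X, y, 1.0, self.params, seed=0)
        p = self.params.as_xgb_params()
        p["seed"] = 0
        plain = xgb.train(p, xgb.DMatrix(X, label=y), num_boost_round=40)
        a = weighted.predict(xgb.DMatrix(X))
        b = plain.predict(xgb.DMatrix(X))
        assert a == pytest.approx(b, abs=1e-12)

    def test_instance_weights_equal_scaled_gradient_objective(self):
        """Per-instance weights reproduce the weighted log-loss gradient update."""
        X, y = two_cluster_data(seed=4)
        w_pos = 7.0
        via_weights = mdl.train_cost_sensitive_gbt(X, y, w_pos, self.params, seed=0)

        def weighted_obj(preds, dtrain):
            yy = dtrain.get_label()
            p = 1.0 / (1.0 + np.exp(-preds))
            w = np.where(yy == 1, w_pos, 1.0)
            return (p - yy) * w, np.maximum(p * (1 - p), 1e-16) * w

        prm = self.params.as_xgb_params()
        prm["seed"] = 0
        prm.pop("objective")
        # raw-margin start equivalent to the builtin's base_score = 0.5
        prm["base_score"] = 0.0
        via_obj = xgb.train(
            prm, xgb.DMatrix(X, label=y), num_boost_round=40, obj=weighted_obj
        )
        a = via_weights.predict(xgb.DMatrix(X))
        margins = via_obj.predict(xgb.DMatrix(X), output_margin=True)
        b = 1.0 / (1.0 + np.exp(-margins))
        assert a == pytest.approx(b, rel=1e-5, abs=1e-6)

    def test_weighted_gradient_hand_value(self):
        # y = 1, sigma(margin) = 0.3, w_pos = 5 -> gradient (0.3 - 1) * 5
        p = 0.3
        w_pos = 5.0
        grad = (p - 1.0) * w_pos
        assert grad == pytest.approx(-3.5)

    def test_separable_data_reaches_high_training_auc(self):
        from sklearn.metrics import roc_auc_score

        X, y = two_cluster_data(n_neg=100, n_pos=30, d=2, sep=4.0, seed=5)
        booster = mdl.train_cost_sensitive_gbt(X, y, 3.0, self.params, seed=1)
        scores = booster.predict(xgb.DMatrix(X))
        assert roc_auc_score(y, scores) > 0.99

    def test_non_finite_features_rejected(self):
        X, y = two_cluster_data()
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mdl.train_cost_sensitive_gbt(X, y, 1.0, self.params, seed=0)


class TestOptimalThreshold:
    def test_hand_case(self):
        th, j = mdl.optimal_threshold(
            np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])
        )
        assert j == pytest.approx(0.5)
        assert th == pytest.approx(0.35)

    def test_perfect_separation(self):
        _, j = mdl.optimal_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert j == pytest.approx(1.0)

    def test_identical_scores(self):
        _, j = mdl.optimal_threshold(np.full(6, 0.5), np.array([0, 1, 0, 1, 0, 1]))
        assert j == pytest.approx(0.0)

    def test_single_class_is_hard_error(self):
        with pytest.raises(ValueError):
            mdl.optimal_threshold(np.array([0.2, 0.4]), np.array([1, 1]))

    def test_matches_bruteforce_grid_on_random_instances(self):
        rng = np.random.default_rng(42)
        grid = np.arange(0.0, 1.0001, 1e-4)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 3)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            th, j = mdl.optimal_threshold(scores, y)
            pred = scores[None, :] >= grid[:, None]
            sens = pred[:, y == 1].mean(axis=1)
            spec = (~pred)[:, y == 0].mean(axis=1)
            assert j == pytest.approx(float((sens + spec - 1).max()), abs=1e-9)

    def test_midpoint_tie_break_centres_optimal_interval(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        th_small, _ = mdl.optimal_threshold(scores, y, tie="smallest")
        th_mid, _ = mdl.optimal_threshold(scores, y, tie="midpoint")
        # smallest attaining score is 0.8; the optimal interval spans
        # (0.2, 0.8] whose candidate midpoint sits at 0.65
        assert th_small == pytest.approx(0.8)
        assert th_mid == pytest.approx(0.65)


class TestPredictAndSerialization:
    def _model(self, threshold=0.5):
        X, y = two_cluster_data(seed=6)
        m = mdl.fit_pipeline(
            X, y, ImbalanceConfig(), BoostParams(n_estimators=30, max_depth=3), seed=0
        )
        return dataclasses.replace(m, threshold=threshold), X

    def test_threshold_extremes(self):
        m, X = self._model(threshold=0.0)
        _, labels = mdl.predict(m, X)
        assert labels.all()
        m1 = dataclasses.replace(m, threshold=1.0)
        proba, labels = mdl.predict(m1, X)
        assert proba.max() < 1.0 and not labels.any()

    def test_roundtrip_is_bit_faithful(self, tmp_path):
        m, X = self._model()
        path = tmp_path / "model.json"
        mdl.save_model(m, path)
        m2 = mdl.load_model(path)
        p1, _ = mdl.predict(m, X)
        p2, _ = mdl.predict(m2, X)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert m2.feature_names == m.feature_names
        assert m2.threshold == m.threshold

    def test_foreign_file_rejected(self, tmp_path):
        path = tmp_path / "nope.json"
        path.write_text('{"schema": "something-else"}')
        with pytest.raises(ValueError, match="artifact"):
            mdl.load_model(path)

    def test_dimension_mismatch_is_hard_error(self):
        m, X = self._model()
        with pytest.raises(ValueError, match="dimension"):
            mdl.predict(m, X[:, :2])


class TestCalibration:
    def _generic(self):
        X, y = two_cluster_data(n_neg=200, n_pos=20, seed=7)
        return (
            mdl.fit_pipeline(
                X, y, ImbalanceConfig(), BoostParams(n_estimators=30, max_depth=3),
                seed=0, threshold=0.4,
            ),
            X,
            y,
        )

    def test_empty_calibration_set_is_identity(self):
        m, _, _ = self._generic()
        assert mdl.calibrate_subject(m, np.empty((0, 4)), np.empty(0), seed=0) is m

    def test_single_class_set_skips_both_steps(self):
        m, X, y = self._generic()
        out = mdl.calibrate_subject(m, X[y == 0][:10], y[y == 0][:10], seed=0)
        assert out.threshold == m.threshold
        assert "single-class" in out.metadata["calibration"]
        p1, _ = mdl.predict(m, X[:5])
        p2, _ = mdl.predict(out, X[:5])
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_two_class_set_appends_trees_and_never_lowers_threshold(self):
        m, X, y = self._generic()
        rng = np.random.default_rng(8)
        idx = np.concatenate([np.flatnonzero(y == 0)[:24], np.flatnonzero(y == 1)[:6]])
        out = mdl.calibrate_subject(m, X[idx] + rng.normal(0, 0.1, (30, 4)), y[idx], seed=0)
        assert "appended" in out.metadata["calibration"]
        assert out.threshold >= m.threshold
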