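"""Sparse trait models: max-features rule, LOOCV leakage, pattern expression."""

import numpy as np
import pytest

from conftest import make_feature_table, make_model
from dynconn.model import (TraitModel, evaluate, fit_lasso_max_features,
                           loocv_predict, pattern_expression)


class TestFitMaxFeatures:
    def test_noiseless_linear_recovery(self, rng):
        X = rng.random((200, 3))
        y = 2.0 * X[:, 0]
        tab = make_feature_table(X)
        model = fit_lasso_max_features(tab, y)
        assert np.argmax(np.abs(model.weights)) == 0
        r = evaluate(y, loocv_predict(tab, y))
        assert r >= 0.99

    def test_sparsity_bound_at_paper_scale(self, rng):
        # n_train = 84, p = 280: active set never exceeds the sample size
        X = rng.random((84, 280))
        y = X[:, :5] @ rng.standard_normal(5) + 0.5 * rng.standard_normal(84)
        model = fit_lasso_max_features(make_feature_table(X), y)
        assert 0 < np.count_nonzero(model.weights) <= 84

    def test_constant_feature_dropped_with_warning(self, rng):
        X = rng.random((30, 4))
        X[:, 2] = 7.0
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        with pytest.warns(UserWarning, match="constant feature"):
            model = fit_lasso_max_features(make_feature_table(X), y)
        assert len(model.edge_ids) == 3

    def test_constant_outcome_rejected(self, rng):
        tab = make_feature_table(rng.random((20, 3)))
        with pytest.raises(ValueError, match="constant"):
            fit_lasso_max_features(tab, np.ones(20))

    def test_support_recovery_high_snr(self, rng):
        # 5 signal edges among 100: >=4 recovered in >=90% of 50 replicates
        hits = 0
        for _ in range(50):
            u = rng.standard_normal(60)
            X = rng.random((60, 100))
            # each signal feature mixes the latent with its own noise, so
            # the five carry overlapping but not redundant information
            X[:, :5] = 0.5 * (u - u.min())[:, None] + rng.random((60, 5))
            y = u + 0.2 * rng.standard_normal(60)
            model = fit_lasso_max_features(make_feature_table(X), y)
            hits += np.count_nonzero(model.weights[:5]) >= 4
        assert hits >= 45

    def test_null_calibration(self, rng):
        # outcome independent of features: mean LOOCV r centers on 0.
        # 60 replicates keep the run short; the bound is ~3 standard errors
        # of the replicate mean (per-replicate sd of r is about 0.25)
        rs = []
        for _ in range(60):
            tab = make_feature_table(rng.random((60, 100)))
            y = rng.standard_normal(60)
            try:
                rs.append(evaluate(y, loocv_predict(tab, y)))
            except ValueError:
                rs.append(0.0)
        assert abs(np.mean(rs)) <= 0.1


class TestLoocv:
    def test_held_out_outcome_cannot_leak(self, rng):
        X = rng.random((12, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(12)
        tab = make_feature_table(X)
        base = loocv_predict(tab, y)
        y2 = y.copy()
        y2[3] += 100.0  # perturb one held-out outcome
        assert loocv_predict(tab, y2)[3] == base[3]

    def test_prediction_order_matches_input(self, rng):
        X = rng.random((15, 3))
        y = X[:, 1]
        preds = loocv_predict(make_feature_table(X), y)
        assert preds.shape == (15,)

    def test_null_cohort_rarely_exceeds_chance(self, rng):
        ok = 0
        for _ in range(100):
            tab = make_feature_table(rng.random((30, 20)))
            y = rng.standard_normal(30)
            try:
                r = evaluate(y, loocv_predict(tab, y))
            except ValueError:
                r = 0.0
            ok += abs(r) <= 0.55  # |r| this large is rare under the null
        assert ok >= 95


class TestPatternExpression:
    def test_training_table_reproduces_fitted_values(self, rng):
        X = rng.random((40, 6))
        y = X[:, 0] - X[:, 3] + 0.1 * rng.standard_normal(40)
        tab = make_feature_table(X)
        model = fit_lasso_max_features(tab, y)
        scores = pattern_expression(model, tab)
        Z = (X - model.feature_means) / model.feature_sds
        np.testing.assert_allclose(scores, Z @ model.weights + model.intercept,
                                   atol=1e-12)

    def test_dead_feature_invariance(self, rng):
        model = make_model([1.0, 0.0, -2.0])
        X = rng.random((10, 3))
        base = pattern_expression(model, make_feature_table(X))
        X2 = X.copy()
        X2[:, 1] += 42.0  # zero-weight feature
        np.testing.assert_array_equal(
            base, pattern_expression(model, make_feature_table(X2)))

    def test_raw_scale_affine_equivalence(self, rng):
        model = make_model([0.5, -1.0, 2.0], means=[1.0, 2.0, 3.0],
                           sds=[0.5, 2.0, 1.5])
        X = rng.random((25, 3)) + 2.0
        tab = make_feature_table(X)
        scores = pattern_expression(model, tab)
        # fold standardization into raw-scale weights: w' = w/sd,
        # b' = b - sum(w*mean/sd)
        w_raw = model.weights / model.feature_sds
        b_raw = model.intercept - np.sum(model.weights * model.feature_means
                                         / model.feature_sds)
        np.testing.assert_allclose(scores, X @ w_raw + b_raw, atol=1e-10)

    def test_extra_columns_ignored_missing_nonzero_rejected(self, rng):
        model = make_model([1.0, -1.0])
        X3 = rng.random((8, 3))
        scores = pattern_expression(model, make_feature_table(X3))
        assert scores.shape == (8,)
        one_col = make_feature_table(X3[:, :1])
        with pytest.raises(KeyError):
            pattern_expression(model, one_col)

    def test_json_round_trip(self, tmp_path, rng):
        X = rng.random((30, 5))
        y = X[:, 2] + 0.1 * rng.standard_normal(30)
        tab = make_feature_table(X)
        model = fit_lasso_max_features(tab, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = TraitModel.from_json(path)
        np.testing.assert_allclose(
            pattern_expression(loaded, tab), pattern_expression(model, tab),
            atol=1e-10)


class TestEvaluate:
    def test_perfect_and_inverted_predictions(self, rng):
        y = rng.standard_normal(20)
        assert evaluate(y, y) == pytest.approx(1.0)
        assert evaluate(y, -y) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 100.0])
        # hand computation from the product-moment definition
        expect = ((a - a.mean()) @ (b - b.mean())) / (
            np.sqrt(((a - a.mean()) ** 2).sum())
            * np.sqrt(((b - b.mean()) ** 2).sum()))
        assert evaluate(a, b) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("bad", [(np.ones(5), None), (None, np.ones(5))])
    def test_constant_vector_rejected(self, rng, bad):
        y = rng.standard_normal(5)
        y_true = bad[0] if bad[0] is not None else y
        y_pred = bad[1] if bad[1] is not None else y
        with pytest.raises(ValueError):
            evaluate(y_true, y_pred)
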