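import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabopls.errors import DegenerateModelError, SchemaError
from metabopls.pls import (
    fit_autoscaled_pls1,
    fit_pls1,
    fit_stats,
    predict,
    vip,
)
from metabopls.preprocess import autoscale


def centered(rng, n, p):
    Z = rng.normal(size=(n, p))
    return Z - Z.mean(axis=0)


def textbook_pls1(Z, y, A):
    """Independent sequential-deflation reference implementation."""
    X_res, y_res = Z.copy(), y.astype(float).copy()
    W, T, P, q = [], [], [], []
    for _ in range(A):
        w = X_res.T @ y_res
        w = w / np.linalg.norm(w)
        t = X_res @ w
        p_a = X_res.T @ t / (t @ t)
        q_a = float(y_res @ t) / (t @ t)
        X_res = X_res - np.outer(t, p_a)
        y_res = y_res - q_a * t
        W.append(w), T.append(t), P.append(p_a), q.append(q_a)
    return map(np.array, (W, T, P, q))


class TestFitPLS1:
    def test_single_column_signal(self, rng):
        raw = rng.normal(size=(12, 5))
        Z = np.linalg.qr(raw - raw.mean(axis=0))[0]  # orthogonal columns
        y = 3.0 * Z[:, 2]
        model = fit_pls1(Z, y, A=1)
        r2, rmsec = fit_stats(model, y)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert np.argmax(np.abs(model.coef)) == 2

    def test_equals_ols_at_full_rank(self, rng):
        for _ in range(10):
            Z = centered(rng, 20, 4)
            y = rng.normal(size=20)
            y = y - y.mean()
            model = fit_pls1(Z, y, A=4)
            ols = Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            np.testing.assert_allclose(Z @ model.coef, ols, atol=1e-8)

    def test_first_weight_is_covariance_direction(self, rng):
        Z = centered(rng, 15, 6)
        y = rng.normal(size=15)
        model = fit_pls1(Z, y, A=2)
        direction = Z.T @ y
        cosine = model.W[:, 0] @ direction / np.linalg.norm(direction)
        assert cosine == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_deflation(self, rng):
        Z = centered(rng, 14, 6)
        y = rng.normal(size=14)
        y -= y.mean()
        model = fit_pls1(Z, y, A=3)
        W, T, P, q = textbook_pls1(Z, y, 3)
        np.testing.assert_allclose(model.W, W.T, atol=1e-10)
        np.testing.assert_allclose(model.T, T.T, atol=1e-10)
        np.testing.assert_allclose(model.q, q, atol=1e-10)

    def test_coefficient_form_equals_deflation_fit(self, rng):
        Z = centered(rng, 16, 7)
        y = rng.normal(size=16)
        y -= y.mean()
        model = fit_pls1(Z, y, A=3)
        sequential = model.T @ model.q
        np.testing.assert_allclose(Z @ model.coef, sequential, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        model = fit_pls1(centered(rng, 20, 8), rng.normal(size=20), A=4)
        T = model.T
        for a in range(4):
            for b in range(a + 1, 4):
                cos = abs(T[:, a] @ T[:, b]) / (
                    np.linalg.norm(T[:, a]) * np.linalg.norm(T[:, b])
                )
                assert cos < 1e-8

    def test_weights_unit_norm(self, rng):
        model = fit_pls1(centered(rng, 10, 5), rng.normal(size=10), A=2)
        np.testing.assert_allclose(
            np.linalg.norm(model.W, axis=0), [1.0, 1.0], atol=1e-12
        )

    def test_r2_non_decreasing_in_A(self, rng):
        Z = centered(rng, 25, 6)
        y = rng.normal(size=25)
        y -= y.mean()
        r2s = [fit_stats(fit_pls1(Z, y, A), y)[0] for A in range(1, 6)]
        assert np.all(np.diff(r2s) >= -1e-12)

    def test_rank_exhausted_names_achieved_count(self, rng):
        Z = centered(rng, 10, 1)
        y = Z[:, 0].copy()
        with pytest.raises(DegenerateModelError, match="1 component"):
            fit_pls1(np.column_stack([Z, Z]), y, A=2)

    def test_invalid_A(self, rng):
        with pytest.raises(DegenerateModelError):
            fit_pls1(centered(rng, 5, 3), rng.normal(size=5), A=5)

    def test_matches_sklearn(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.gamma(3.0, 10.0, size=(18, 6))
        y = rng.uniform(10, 90, size=18)
        ours = fit_autoscaled_pls1(X, y, A=2)
        ref = PLSRegression(n_components=2, scale=True).fit(X, y)
        np.testing.assert_allclose(
            ours.fitted, ref.predict(X).ravel(), atol=1e-8
        )


class TestPredict:
    def test_training_predictions_equal_fitted(self, rng):
        X = rng.gamma(2.0, 20.0, size=(12, 5))
        y = rng.uniform(0, 100, size=12)
        model = fit_autoscaled_pls1(X, y, A=2)
        np.testing.assert_allclose(predict(model, X), model.fitted, atol=1e-12)

    def test_mean_observation_predicts_mean_response(self, rng):
        X = rng.gamma(2.0, 20.0, size=(12, 5))
        y = rng.uniform(0, 100, size=12)
        model = fit_autoscaled_pls1(X, y, A=2)
        assert predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_feature_permutation_invariance(self, rng):
        X = rng.gamma(2.0, 20.0, size=(14, 6))
        y = rng.uniform(0, 100, size=14)
        perm = rng.permutation(6)
        model = fit_autoscaled_pls1(X, y, A=2)
        model_p = fit_autoscaled_pls1(X[:, perm], y, A=2)
        new = rng.gamma(2.0, 20.0, size=(3, 6))
        np.testing.assert_allclose(
            predict(model, new), predict(model_p, new[:, perm]), atol=1e-8
        )

    def test_missing_feature_rejected(self, rng):
        X = rng.gamma(2.0, 20.0, size=(10, 4))
        model = fit_autoscaled_pls1(X, rng.uniform(0, 100, size=10), A=1)
        with pytest.raises(SchemaError):
            predict(model, X[:, :3])

    def test_out_of_range_predictions_not_clipped(self, rng):
        X = rng.gamma(2.0, 20.0, size=(10, 3))
        y = np.linspace(1, 99, 10)
        model = fit_autoscaled_pls1(X, y, A=1)
        extreme = X.max(axis=0) * 100
        # just check it returns a number rather than clamping silently
        assert np.isfinite(predict(model, extreme)[0])


class TestVIP:
    def test_single_predictor_is_one(self, rng):
        Z = centered(rng, 10, 1)
        model = fit_pls1(Z, Z[:, 0] * 2, A=1)
        assert vip(model).vip[0] == pytest.approx(1.0)

    def test_one_hot_analytic_case(self):
        # orthonormal columns, y equal to column 3: VIP_3 = sqrt(p)
        raw = np.random.default_rng(5).normal(size=(12, 4))
        Z = np.linalg.qr(raw - raw.mean(axis=0))[0]  # orthonormal, zero-mean
        y = Z[:, 3].copy()
        model = fit_pls1(Z, y, A=1)
        profile = vip(model)
        assert profile.vip[3] == pytest.approx(np.sqrt(4), abs=1e-10)
        assert np.all(profile.vip[:3] < 1e-10)

    def test_direct_formula_oracle(self, rng):
        Z = centered(rng, 15, 6)
        y = rng.normal(size=15)
        y -= y.mean()
        model = fit_pls1(Z, y, A=2)
        W, T, P, q = textbook_pls1(Z, y, 2)
        ssy = np.array([q[a] ** 2 * (T[a] @ T[a]) for a in range(2)])
        expected = np.sqrt(6 * (W.T**2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(vip(model).vip, expected, atol=1e-10)

    def test_dropped_features_get_zero(self, rng):
        X = rng.gamma(2.0, 5.0, size=(10, 4))
        X[:, 1] = 7.0  # constant column
        model = fit_autoscaled_pls1(X, rng.uniform(0, 100, size=10), A=1)
        profile = vip(model)
        assert profile.vip[1] == 0.0
        assert profile.dropped.tolist() == [1]

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(6, 25),
        p=st.integers(2, 10),
        A=st.integers(1, 3),
    )
    def test_vip_normalization_property(self, seed, n, p, A):
        rng = np.random.default_rng(seed)
        A = min(A, min(n - 1, p))
        Z = centered(rng, n, p)
        y = rng.normal(size=n)
        y -= y.mean()
        try:
            model = fit_pls1(Z, y, A=A)
            profile = vip(model)
        except DegenerateModelError:
            return
        assert np.sum(profile.vip**2) == pytest.approx(p, abs=1e-8)


class TestFitStats:
    def test_perfect_fit(self, rng):
        Z = centered(rng, 10, 3)
        beta = np.array([1.0, -2.0, 0.5])
        y = Z @ beta
        model = fit_pls1(Z, y, A=3)
        r2, rmsec = fit_stats(model, y)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert rmsec == pytest.approx(0.0, abs=1e-8)

    def test_null_model_r2_near_zero(self, rng):
        Z = centered(rng, 12, 2)
        ortho = rng.normal(size=12)
        ortho -= ortho.mean()
        ortho -= Z @ np.linalg.lstsq(Z, ortho, rcond=None)[0]
        y = ortho + 1e-6 * Z[:, 0]
        model = fit_pls1(Z, y, A=1)
        r2, _ = fit_stats(model, y)
        assert 0 <= r2 < 1e-8

    def test_matches_residual_arithmetic(self, rng):
        X = rng.gamma(2.0, 10.0, size=(14, 5))
        y = rng.uniform(0, 100, size=14)
        model = fit_autoscaled_pls1(X, y, A=2)
        r2, rmsec = fit_stats(model, y)
        rss = np.sum((y - model.fitted) ** 2)
        assert r2 == pytest.approx(1 - rss / np.sum((y - y.mean()) ** 2))
        assert rmsec == pytest.approx(np.sqrt(rss / 14))

    def test_zero_variance_response_errors(self, rng):
        Z = centered(rng, 8, 3)
        model = fit_pls1(Z, rng.normal(size=8), A=1)
        with pytest.raises(DegenerateModelError):
            fit_stats(model, np.full(8, 42.0))


class TestAutoscaledWrapper:
    def test_zero_variance_response_rejected(self, rng):
        X = rng.gamma(2.0, 10.0, size=(8, 3))
        with pytest.raises(DegenerateModelError):
            fit_autoscaled_pls1(X, np.full(8, 10.0), A=1)

    def test_scaling_stored_for_prediction(self, rng):
        X = rng.gamma(2.0, 10.0, size=(10, 4))
        y = rng.uniform(0, 100, size=10)
        model = fit_autoscaled_pls1(X, y, A=1)
        Z, params = autoscale(X)
        manual = model.y_mean + model.y_sd * (params.transform(X) @ model.coef)
        np.testing.assert_allclose(predict(model, X), manual, atol=1e-12)
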