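"""PLS1 regression, PRESS model selection, LOOCV and error metrics."""

import numpy as np
import pytest

from bmiconn.errors import DegenerateInputError, InvalidArgumentError
from bmiconn.plsr import (
    error_metrics,
    fit_fold,
    fit_plsr,
    loocv_predict,
    predict,
    press,
    press_curve,
    select_n_lv,
    simple_feature_r2,
)


def linear_problem(rng, n=40, p=5, noise=0.0):
    X = rng.standard_normal((n, p))
    beta = rng.uniform(0.5, 2.0, p)
    y = X @ beta + 3.0 + noise * rng.standard_normal(n)
    return X, y


class TestFitPredict:
    def test_exact_linear_recovery(self, rng):
        X, y = linear_problem(rng)
        model = fit_plsr(X, y, 5)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)
        assert model.explained_variance_y == pytest.approx(1.0, abs=1e-10)

    def test_single_feature_equals_ols_line(self, rng):
        X = rng.standard_normal((30, 1))
        y = 2.0 * X[:, 0] + rng.standard_normal(30)
        model = fit_plsr(X, y, 1)
        slope, intercept = np.polyfit(X[:, 0], y, 1)
        np.testing.assert_allclose(predict(model, X), slope * X[:, 0] + intercept, atol=1e-8)

    def test_full_rank_max_lv_equals_multiple_ols(self, rng):
        X, y = linear_problem(rng, noise=1.0)
        model = fit_plsr(X, y, 5)
        Xd = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(predict(model, X), Xd @ beta, atol=1e-6)

    def test_matches_sklearn_pls(self, rng):
        """Independent cross-check against scikit-learn's PLSRegression."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        X, y = linear_problem(rng, n=50, p=8, noise=1.0)
        model = fit_plsr(X, y, 3)
        sk = sklearn_pls(n_components=3, scale=True).fit(X, y)
        np.testing.assert_allclose(
            predict(model, X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_training_ev_monotone_press_not(self, rng):
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)  # pure noise
        evs = [fit_plsr(X, y, k).explained_variance_y for k in range(1, 7)]
        assert np.all(np.diff(evs) >= -1e-12)
        curve = press_curve(X, y, 6)
        assert np.any(np.diff(curve) > 0)  # PRESS eventually worsens on noise

    def test_prediction_at_column_means_is_y_mean(self, rng):
        X, y = linear_problem(rng, noise=0.5)
        model = fit_plsr(X, y, 3)
        assert predict(model, X.mean(0)[None, :])[0] == pytest.approx(model.y_mean, abs=1e-10)

    def test_training_prediction_reproduces_fit_and_batching(self, rng):
        X, y = linear_problem(rng, noise=0.5)
        model = fit_plsr(X, y, 2)
        batch = predict(model, X)
        rows = np.array([predict(model, X[i : i + 1])[0] for i in range(len(y))])
        np.testing.assert_allclose(batch, rows, atol=1e-12)

    def test_constant_column_named(self, rng):
        X, y = linear_problem(rng)
        X[:, 2] = 5.0
        with pytest.raises(DegenerateInputError, match="column 2"):
            fit_plsr(X, y, 2)

    def test_bad_n_lv_rejected(self, rng):
        X, y = linear_problem(rng)
        with pytest.raises(InvalidArgumentError):
            fit_plsr(X, y, 50)
        model = fit_plsr(X, y, 2)
        with pytest.raises(InvalidArgumentError):
            predict(model, X[:, :3])


class TestPress:
    def test_noiseless_press_near_zero(self, rng):
        X, y = linear_problem(rng)
        assert press(X, y, 5) < 1e-10 * np.sum((y - y.mean()) ** 2)

    def test_equals_naive_refit_loop(self, rng):
        X, y = linear_problem(rng, n=25, p=4, noise=1.0)
        naive = np.zeros(4)
        for i in range(25):
            mask = np.ones(25, dtype=bool)
            mask[i] = False
            model = fit_plsr(X[mask], y[mask], 4)
            for k in range(1, 5):
                naive[k - 1] += (y[i] - predict(model, X[i : i + 1], n_lv=k)[0]) ** 2
        np.testing.assert_allclose(press_curve(X, y, 4), naive, rtol=1e-9)

    def test_noise_press_rarely_improves_late(self):
        """On pure noise, PRESS should not keep improving with extra LVs."""
        rng = np.random.default_rng(42)
        non_improving = 0
        reps = 40
        for _ in range(reps):
            X = rng.standard_normal((30, 8))
            y = rng.standard_normal(30)
            curve = press_curve(X, y, 6)
            if np.argmin(curve) + 1 <= 3:
                non_improving += 1
        assert non_improving / reps >= 0.8


class TestSelectNLv:
    def test_first_non_improvement(self):
        assert select_n_lv(None, None, 3, curve=np.array([10.0, 8.0, 9.0])) == 2

    def test_strictly_decreasing_returns_max(self):
        assert select_n_lv(None, None, 3, curve=np.array([10.0, 8.0, 7.0])) == 3

    def test_global_minimum_criterion(self):
        curve = np.array([10.0, 8.0, 9.0, 5.0])
        assert select_n_lv(None, None, 4, criterion="min", curve=curve) == 4

    def test_unknown_criterion_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_n_lv(None, None, 2, criterion="aic", curve=np.array([1.0, 2.0]))


class TestSimpleFeatureR2:
    def test_exact_line(self):
        x = np.arange(10.0)
        r2, p = simple_feature_r2(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_feature(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        y = y - y.mean()
        if abs(np.corrcoef(x, y)[0, 1]) > 1e-12:
            y = y - x * (x @ y) / (x @ x)
        r2, _ = simple_feature_r2(x, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # deviations x: {-1.5,-0.5,.5,1.5}, y: {-.5,-1.5,1.5,.5};
        # r = 3 / sqrt(5*5) = 0.6, R^2 = 0.36
        r2, _ = simple_feature_r2(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3]))
        assert r2 == pytest.approx(0.36, abs=1e-12)

    def test_constant_feature_rejected(self):
        with pytest.raises(DegenerateInputError):
            simple_feature_r2(np.ones(6), np.arange(6.0))


class TestLoocv:
    def test_noiseless_linear_near_perfect(self, rng):
        X, y = linear_problem(rng, n=20, p=3)
        report = loocv_predict(X, y, 3)
        assert report.percent_error < 0.1
        assert report.pearson_r > 0.999

    def test_report_shapes(self, rng):
        X, y = linear_problem(rng, n=15, p=4, noise=1.0)
        report = loocv_predict(X, y, 4)
        assert len(report.predicted) == 15
        assert len(report.per_fold_n_lv) == 15

    def test_holdout_leakage_guard(self, rng):
        """Corrupting the held-out row must not change that fold's model."""
        X, y = linear_problem(rng, n=20, p=4, noise=1.0)
        model_a, k_a = fit_fold(X, y, 7, max_lv=4)
        X_corrupt = X.copy()
        X_corrupt[7] = 1e6
        model_b, k_b = fit_fold(X_corrupt, y, 7, max_lv=4)
        assert k_a == k_b
        np.testing.assert_array_equal(model_a.coef, model_b.coef)
        np.testing.assert_array_equal(model_a.x_mean, model_b.x_mean)


class TestErrorMetrics:
    def test_perfect_prediction(self):
        assert error_metrics(np.array([20.0, 30.0]), np.array([20.0, 30.0])) == (0.0, 0.0)

    def test_hand_values(self):
        rms, pct = error_metrics(np.array([20.0, 30.0]), np.array([22.0, 27.0]))
        assert rms == pytest.approx(np.sqrt(6.5), rel=1e-12)
        assert pct == pytest.approx(10.0, rel=1e-12)

    def test_order_invariance(self, rng):
        a = rng.uniform(18, 40, 20)
        p = a + rng.standard_normal(20)
        perm = rng.permutation(20)
        assert error_metrics(a, p)[0] == pytest.approx(error_metrics(a[perm], p[perm])[0])

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(InvalidArgumentError):
            error_metrics(np.array([0.0, 30.0]), np.array([1.0, 2.0]))
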