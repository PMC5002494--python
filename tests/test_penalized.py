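import warnings

import numpy as np
import pytest
import statsmodels.api as sm

from fdrsis.datagen import LabeledData
from fdrsis.penalized import (
    PenalizedLogit,
    PenaltySpec,
    coordinate_minimizer,
    cv_select_lambda,
    fit_penalized_logistic,
    lambda_path,
    penalty_value,
    stratified_folds,
)


def _grid_argmin(z, v, spec, half_width=None, npts=400_001):
    """Dense-grid oracle for the one-coordinate surrogate minimiser."""
    B = half_width or max(abs(z) / v * 1.2 + 1.0,
                          (spec.gamma if spec.family != "lasso" else 1.0)
                          * max(spec.lam, 1e-8) * 1.2)
    b = np.linspace(-B, B, npts)
    h = 0.5 * v * b**2 - z * b + penalty_value(spec, b)
    return b[int(np.argmin(h))]


class TestPenaltyValue:
    @pytest.mark.parametrize(
        "family, lam, gamma, b, expected",
        [
            ("lasso", 0.5, np.nan, 2.0, 1.0),
            ("mcp", 1.0, 3.0, 5.0, 1.5),
            ("scad", 1.0, 3.7, 0.5, 0.5),
            ("scad", 1.0, 3.7, 10.0, 2.35),
        ],
    )
    def test_closed_form_values(self, family, lam, gamma, b, expected):
        assert penalty_value(PenaltySpec(family, lam, gamma), b) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize("family,gamma", [("lasso", np.nan), ("scad", 3.7),
                                              ("mcp", 3.0)])
    def test_zero_at_origin_and_continuous(self, family, gamma):
        spec = PenaltySpec(family, 0.8, gamma)
        assert penalty_value(spec, 0.0) == 0.0
        b = np.linspace(-5, 5, 20_001)
        vals = penalty_value(spec, b)
        assert np.all(vals >= 0)
        assert np.abs(np.diff(vals)).max() < 0.01  # no jumps

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            PenaltySpec("scad", 0.5, 1.5)
        with pytest.raises(ValueError):
            PenaltySpec("mcp", 0.5, 0.9)
        with pytest.raises(ValueError):
            PenaltySpec("lasso", -0.1)


class TestCoordinateMinimizer:
    @pytest.mark.parametrize(
        "family, gamma, z, v, lam, expected",
        [
            ("lasso", np.nan, 3.0, 1.0, 1.0, 2.0),
            ("lasso", np.nan, 0.5, 1.0, 1.0, 0.0),
            ("mcp", 3.0, 10.0, 1.0, 1.0, 10.0),
        ],
    )
    def test_closed_form_cases(self, family, gamma, z, v, lam, expected):
        spec = PenaltySpec(family, lam, gamma)
        assert coordinate_minimizer(z, v, spec) == pytest.approx(expected)

    def test_grid_oracle_agreement(self):
        gen = np.random.default_rng(12)
        for _ in range(1000):
            family = gen.choice(["lasso", "scad", "mcp"])
            gamma = {"lasso": np.nan, "scad": gen.uniform(2.1, 6),
                     "mcp": gen.uniform(1.2, 5)}[family]
            spec = PenaltySpec(family, gen.uniform(0.01, 1.5), gamma)
            z = gen.uniform(-4, 4)
            v = gen.uniform(0.4, 2.0) if family != "lasso" else gen.uniform(0.05, 2)
            if family == "mcp" and v <= 1 / spec.gamma:
                continue  # fallback branch covered separately
            b_hat = coordinate_minimizer(z, v, spec)
            b_ref = _grid_argmin(z, v, spec)
            h = lambda b: 0.5 * v * b**2 - z * b + penalty_value(spec, b)
            assert h(b_hat) <= h(b_ref) + 1e-8
            assert abs(b_hat - b_ref) < 1e-4 or abs(h(b_hat) - h(b_ref)) < 1e-8

    def test_mcp_low_curvature_fallback_warns(self):
        spec = PenaltySpec("mcp", 1.0, 3.0)
        with pytest.warns(RuntimeWarning, match="grid search"):
            b = coordinate_minimizer(0.5, 0.2, spec)  # v < 1/gamma
        b_ref = _grid_argmin(0.5, 0.2, spec)
        assert b == pytest.approx(b_ref, abs=1e-3)


class TestFit:
    def test_null_model_at_lam_max(self, tiny_dense_data):
        m = PenalizedLogit.from_labeled_data(tiny_dense_data)
        for family, gamma in [("lasso", np.nan), ("scad", 3.7), ("mcp", 3.0)]:
            fit = m.fit(PenaltySpec(family, m.lam_max * 1.0, gamma))
            assert fit.model_size == 0
            ybar = tiny_dense_data.y.mean()
            assert fit.intercept == pytest.approx(
                np.log(ybar / (1 - ybar)), abs=1e-8
            )

    def test_lam_zero_matches_mle(self, tiny_dense_data):
        ref = sm.Logit(
            tiny_dense_data.y, sm.add_constant(tiny_dense_data.X)
        ).fit(disp=0)
        for family, gamma in [("lasso", np.nan), ("scad", 3.7), ("mcp", 3.0)]:
            fit = fit_penalized_logistic(
                tiny_dense_data, PenaltySpec(family, 0.0, gamma)
            )
            assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
            np.testing.assert_allclose(fit.beta, ref.params[1:], atol=1e-6)

    def test_lasso_kkt_conditions(self, small_signal_data):
        _, _, data = small_signal_data
        m = PenalizedLogit.from_labeled_data(data)
        lam = 0.3 * m.lam_max
        fit = m.fit(PenaltySpec("lasso", lam))
        # KKT on the standardized scale the penalty applies to
        Xs = (data.X - fit.standardization.center) / fit.standardization.scale
        beta_std = fit.beta * fit.standardization.scale
        p = fit.predict_proba(data.X)
        score = Xs.T @ (data.y - p) / data.n
        zero = beta_std == 0
        assert np.all(np.abs(score[zero]) <= lam + 1e-5)
        nz = ~zero
        np.testing.assert_allclose(
            score[nz], lam * np.sign(beta_std[nz]), atol=1e-5
        )

    def test_lasso_matches_sklearn(self, small_signal_data):
        from sklearn.linear_model import LogisticRegression

        _, _, data = small_signal_data
        Xs = (data.X - data.X.mean(0)) / data.X.std(0)
        pre = LabeledData(Xs, data.y)
        lam = 0.08
        fit = fit_penalized_logistic(pre, PenaltySpec("lasso", lam))
        ref = LogisticRegression(
            penalty="l1", C=1.0 / (data.n * lam), solver="saga",
            tol=1e-10, max_iter=50_000, fit_intercept=True,
        ).fit(Xs, data.y)
        np.testing.assert_allclose(fit.beta, ref.coef_[0], atol=2e-4)
        assert fit.intercept == pytest.approx(float(ref.intercept_[0]), abs=2e-4)

    @pytest.mark.parametrize("family,gamma", [("scad", 1e6), ("mcp", 1e6)])
    def test_nonconvex_limits_to_lasso(self, family, gamma, small_signal_data):
        _, _, data = small_signal_data
        m = PenalizedLogit.from_labeled_data(data)
        lam = 0.25 * m.lam_max
        base = m.fit(PenaltySpec("lasso", lam))
        limit = m.fit(PenaltySpec(family, lam, gamma))
        np.testing.assert_allclose(limit.beta, base.beta, atol=1e-4)

    def test_column_permutation_equivariance(self, small_signal_data):
        _, _, data = small_signal_data
        perm = np.random.default_rng(3).permutation(data.P)
        spec = PenaltySpec("mcp", 0.05, 3.0)
        a = fit_penalized_logistic(data, spec)
        b = fit_penalized_logistic(
            LabeledData(data.X[:, perm], data.y), spec
        )
        np.testing.assert_allclose(b.beta, a.beta[perm], atol=1e-6)

    def test_objective_nonincreasing_over_outer_iterations(self, small_signal_data):
        _, _, data = small_signal_data
        m = PenalizedLogit.from_labeled_data(data)
        lam = 0.2 * m.lam_max
        objs = []
        for k in range(1, 8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = m.fit(PenaltySpec("lasso", lam), max_outer=k,
                            warm_path=False)
            objs.append(fit.objective)
        diffs = np.diff(objs)
        assert np.all(diffs <= 1e-10)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            PenalizedLogit(np.ones(20), X)


class TestLambdaPath:
    def test_grid_shape_and_endpoints(self, tiny_dense_data):
        grid = lambda_path(tiny_dense_data, n_lambda=12, ratio=0.05)
        assert grid.size == 12
        assert np.all(np.diff(grid) < 0)
        m = PenalizedLogit.from_labeled_data(tiny_dense_data)
        assert grid[0] == pytest.approx(m.lam_max)
        assert grid[-1] == pytest.approx(0.05 * m.lam_max)
        two = lambda_path(tiny_dense_data, n_lambda=2, ratio=0.1)
        np.testing.assert_allclose(two, [m.lam_max, 0.1 * m.lam_max])

    def test_degenerate_design_rejected(self):
        X = np.ones((30, 3))
        y = np.array([0, 1] * 15)
        with pytest.raises(ValueError):
            lambda_path(LabeledData(X, y))


class TestCV:
    def test_loss_finite_and_choice_on_grid(self, small_signal_data):
        _, _, data = small_signal_data
        res = cv_select_lambda(
            data, "lasso", n_folds=5, rng=np.random.default_rng(0),
            n_lambda=15,
        )
        assert np.all(np.isfinite(res.cv_loss))
        assert res.lam_chosen in res.lam_grid
        assert res.fold_assignment.size == data.n

    def test_folds_stratified(self, rng):
        y = np.array([0] * 30 + [1] * 20)
        folds = stratified_folds(y, 5, rng)
        for k in range(5):
            cls = y[folds == k]
            assert (cls == 0).sum() == 6 and (cls == 1).sum() == 4
        with pytest.raises(ValueError):
            stratified_folds(np.array([0] * 20 + [1] * 2), 5, rng)

    def test_strong_signal_support_recovery(self):
        # N=200, P=50, 5 strong effects: CV-tuned lasso recovers >= 4 of 5
        # true variables in >= 90% of seeds
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            gen = np.random.default_rng(1000 + seed)
            X = gen.standard_normal((200, 50))
            beta = np.zeros(50)
            beta[:5] = [1.5, -1.5, 1.2, -1.2, 1.0]
            p = 1 / (1 + np.exp(-(X @ beta)))
            y = (gen.random(200) < p).astype(int)
            fit = PenalizedLogit(y, X).fit_cv(
                "lasso", n_folds=10, rng=gen, n_lambda=25
            )
            if np.intersect1d(fit.support, np.arange(5)).size >= 4:
                hits += 1
        assert hits / n_seeds >= 0.9
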