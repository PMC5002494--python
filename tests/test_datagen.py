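import numpy as np
import pytest

from fdrsis.datagen import (
    LabeledData,
    SimDesign,
    draw_true_beta,
    gen_covariates,
    generate_balanced,
    read_labeled_data,
    simulate_outcome,
    split_train_test,
    write_labeled_data,
)


class TestSimDesign:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimDesign(P=10, rho=1.0, n_true=2)
        with pytest.raises(ValueError):
            SimDesign(P=10, rho=-0.1, n_true=2)
        with pytest.raises(ValueError):
            SimDesign(P=10, n_true=11)
        with pytest.raises(ValueError):
            SimDesign(P=10, n_true=2, beta_low=2.0, beta_high=-1.0)


class TestTrueBeta:
    def test_support_and_range(self, rng):
        design = SimDesign(P=200, n_true=25, beta_low=-1.5, beta_high=2.0)
        truth = draw_true_beta(design, rng)
        assert np.array_equal(truth.support, np.arange(25))
        nz = truth.beta[:25]
        assert np.all((nz >= -1.5) & (nz <= 2.0)) and np.all(nz != 0)
        assert np.all(truth.beta[25:] == 0)

    def test_null_design(self, rng):
        truth = draw_true_beta(SimDesign(P=50, n_true=0), rng)
        assert truth.support.size == 0 and not truth.beta.any()

    def test_seed_determinism(self):
        design = SimDesign(P=60, n_true=10, seed=5)
        a = draw_true_beta(design, design.rng())
        b = draw_true_beta(design, design.rng())
        assert np.array_equal(a.beta, b.beta)


class TestCovariates:
    def test_independent_columns(self, rng):
        X = gen_covariates(8000, SimDesign(P=6, rho=0.0, n_true=0), rng)
        corr = np.corrcoef(X.T)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    @pytest.mark.parametrize("rho", [0.1, 0.4, 0.8])
    def test_ar1_correlation_and_variance(self, rho, rng):
        # sd of a correlation estimate ~ (1 - rho^2)/sqrt(n)
        n = 10_000
        X = gen_covariates(n, SimDesign(P=8, rho=rho, n_true=0), rng)
        corr = np.corrcoef(X.T)
        tol = 3 * (1 - rho**2) / np.sqrt(n)
        for k in range(7):
            assert corr[k, k + 1] == pytest.approx(rho, abs=max(tol, 0.02))
        # lag-2 decays as rho^2
        assert corr[0, 2] == pytest.approx(rho**2, abs=0.05)
        assert np.allclose(X.var(axis=0), 1.0, atol=0.06)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            gen_covariates(0, SimDesign(P=4, n_true=0), rng)


class TestOutcome:
    def test_logistic_symmetry_and_saturation(self, rng):
        # x.b = 0 -> exactly p = 0.5; huge x.b saturates without overflow
        draws = [
            simulate_outcome(np.zeros(3), np.ones(3), np.random.default_rng(s))
            for s in range(400)
        ]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.07)
        big = [
            simulate_outcome(np.array([50.0]), np.array([1.0]),
                             np.random.default_rng(s))
            for s in range(50)
        ]
        assert all(b == 1 for b in big)

    def test_nonfinite_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_outcome(np.array([np.inf]), np.array([1.0]), rng)
        with pytest.raises(ValueError):
            simulate_outcome(np.array([1.0, 2.0]), np.array([1.0]), rng)


class TestBalancedSampling:
    def test_exact_quotas(self, rng):
        design = SimDesign(P=20, n_cases=37, n_controls=23, n_true=3)
        truth = draw_true_beta(design, rng)
        data = generate_balanced(design, truth, rng)
        assert data.n == 60
        assert int(data.y.sum()) == 37

    def test_minimal_quota(self, rng):
        design = SimDesign(P=2, n_cases=1, n_controls=1, n_true=0)
        truth = draw_true_beta(design, rng)
        data = generate_balanced(design, truth, rng)
        assert data.n == 2 and sorted(data.y) == [0, 1]

    def test_seed_determinism(self):
        design = SimDesign(P=10, n_cases=15, n_controls=15, n_true=2, seed=9)
        runs = []
        for _ in range(2):
            g = design.rng()
            truth = draw_true_beta(design, g)
            runs.append(generate_balanced(design, truth, g))
        assert np.array_equal(runs[0].X, runs[1].X)
        assert np.array_equal(runs[0].y, runs[1].y)

    def test_null_acceptance_rate_balanced(self, rng):
        # with beta = 0 each generated row is a fair coin; quotas fill with
        # roughly 2x the target rows, so both classes appear in order
        design = SimDesign(P=5, n_cases=200, n_controls=200, n_true=0)
        truth = draw_true_beta(design, rng)
        data = generate_balanced(design, truth, rng)
        assert int(data.y.sum()) == 200


class TestSplit:
    def test_sizes_600_300(self, rng):
        design = SimDesign(P=10, n_cases=450, n_controls=450, n_true=0)
        truth = draw_true_beta(design, rng)
        data = generate_balanced(design, truth, rng)
        train, test = split_train_test(data, 600, rng)
        assert (train.n, test.n) == (600, 300)
        # stratified: balanced input stays balanced
        assert int(train.y.sum()) == 300 and int(test.y.sum()) == 150

    def test_boundary_and_errors(self, rng):
        data = LabeledData(np.arange(20.0).reshape(10, 2), [0, 1] * 5)
        train, test = split_train_test(data, 9, rng, stratified=False)
        assert test.n == 1
        with pytest.raises(ValueError):
            split_train_test(data, 10, rng)

    def test_partition_is_disjoint_and_complete(self, rng):
        X = np.arange(60.0).reshape(30, 2)
        data = LabeledData(X, [0, 1] * 15)
        train, test = split_train_test(data, 20, rng)
        combined = np.vstack([train.X, test.X])
        assert np.array_equal(
            np.sort(combined[:, 0]), np.sort(X[:, 0])
        )


def test_tsv_round_trip(tmp_path, rng):
    design = SimDesign(P=7, n_cases=8, n_controls=8, n_true=2)
    truth = draw_true_beta(design, rng)
    data = generate_balanced(design, truth, rng)
    path = tmp_path / "data.tsv"
    write_labeled_data(data, path)
    back = read_labeled_data(path)
    assert back.variable_names == data.variable_names
    assert np.array_equal(back.y, data.y)
    np.testing.assert_allclose(back.X, data.X, rtol=1e-9)
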