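import numpy as np
import pytest

from fdrsis.datagen import LabeledData, SimDesign, draw_true_beta, generate_balanced


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_signal_data():
    """Balanced case-control set, 5 true effects among 100 variables."""
    design = SimDesign(
        P=100, n_cases=150, n_controls=150, rho=0.2, n_true=5, seed=42
    )
    gen = design.rng()
    truth = draw_true_beta(design, gen)
    data = generate_balanced(design, truth, gen)
    return design, truth, data


@pytest.fixture(scope="session")
def tiny_dense_data():
    """Well-conditioned N >> P instance where the unpenalized MLE exists."""
    gen = np.random.default_rng(7)
    n, p = 400, 5
    X = gen.standard_normal((n, p))
    beta = np.array([1.0, -0.8, 0.5, 0.0, 0.0])
    prob = 1 / (1 + np.exp(-(0.3 + X @ beta)))
    y = (gen.random(n) < prob).astype(int)
    return LabeledData(X, y)
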