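"""Synthetic data generation for high-dimensional logistic variable selection.

Covariates follow a stationary Gaussian AR(1) process across columns
(corr(x_k, x_l) = rho^|k-l|, unit marginal variance); a sparse coefficient
vector with uniformly distributed nonzero effects drives a Bernoulli outcome
through the logistic link; case/control quotas are filled by per-row rejection
sampling, mimicking a balanced case-control design over an ultrahigh-
dimensional expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

__all__ = [
    "SimDesign",
    "TruthSpec",
    "LabeledData",
    "draw_true_beta",
    "gen_covariates",
    "simulate_outcome",
    "generate_balanced",
    "split_train_test",
    "write_labeled_data",
    "read_labeled_data",
    "variable_names",
]


def variable_names(P: int) -> list[str]:
    """1-based report labels g01, g02, ... (zero-padded to a common width)."""
    width = max(2, len(str(P)))
    return [f"g{j + 1:0{width}d}" for j in range(P)]


@dataclass(frozen=True)
class SimDesign:
    """Parameters of the simulated case-control study.

    Parameters
    ----------
    P : int
        Number of variables (columns).
    n_cases, n_controls : int
        Class quotas for the balanced design.
    rho : float
        AR(1) correlation between adjacent columns, in [0, 1).
    n_true : int
        Number of truly nonzero coefficients (placed at the first indices).
    beta_low, beta_high : float
        Endpoints of the uniform distribution of the nonzero effects.
    seed : int
        Master seed of the design.
    """

    P: int
    n_cases: int = 450
    n_controls: int = 450
    rho: float = 0.1
    n_true: int = 25
    beta_low: float = -1.5
    beta_high: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be a positive integer")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("class quotas must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.n_true < 0:
            raise ValueError("n_true must be nonnegative")
        if self.n_true > self.P:
            raise ValueError(f"n_true={self.n_true} exceeds P={self.P}")
        if self.n_true > 0 and not self.beta_low < self.beta_high:
            raise ValueError("beta_low must be strictly below beta_high")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TruthSpec:
    """True support and coefficients of a simulated model."""

    support: np.ndarray  # sorted 0-based indices of nonzero coefficients
    beta: np.ndarray  # length-P dense coefficient vector, zero off support

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, dtype=np.intp))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        nz = np.flatnonzero(self.beta)
        if not np.array_equal(np.sort(self.support), nz):
            raise ValueError("beta must be nonzero exactly on the support")


@dataclass
class LabeledData:
    """Feature matrix with a binary outcome — the universal pipeline input."""

    X: np.ndarray
    y: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row count of X must equal length of y")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must contain only 0/1")
        self.y = self.y.astype(np.int8)
        if not self.variable_names:
            self.variable_names = variable_names(self.X.shape[1])
        if len(self.variable_names) != self.X.shape[1]:
            raise ValueError("variable_names length must equal column count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "LabeledData":
        return LabeledData(self.X[idx], self.y[idx], list(self.variable_names))


def draw_true_beta(design: SimDesign, rng: np.random.Generator) -> TruthSpec:
    """Draw the sparse truth: the first ``n_true`` coefficients are i.i.d.
    Uniform(beta_low, beta_high), the rest exactly zero.

    A coefficient that happens to be drawn exactly 0.0 is redrawn so the
    support invariant (nonzero iff in support) holds.
    """
    beta = np.zeros(design.P)
    if design.n_true:
        vals = rng.uniform(design.beta_low, design.beta_high, size=design.n_true)
        while np.any(vals == 0.0):  # pragma: no cover - probability zero
            vals[vals == 0.0] = rng.uniform(
                design.beta_low, design.beta_high, size=np.sum(vals == 0.0)
            )
        beta[: design.n_true] = vals
    return TruthSpec(support=np.arange(design.n_true), beta=beta)


def gen_covariates(
    n_rows: int, design: SimDesign, rng: np.random.Generator
) -> np.ndarray:
    """Generate an (n_rows, P) matrix of AR(1)-correlated standard normals.

    x_1 = z_1 and x_j = rho * x_{j-1} + sqrt(1 - rho^2) * z_j with z_j i.i.d.
    N(0, 1), giving unit marginal variance and corr(x_k, x_l) = rho^|k-l|.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    z = rng.standard_normal((n_rows, design.P))
    if design.rho == 0.0:
        return z
    s = np.sqrt(1.0 - design.rho**2)
    u = z * s
    u[:, 0] = z[:, 0]  # first column keeps unit scale to start stationary
    return lfilter([1.0], [1.0, -design.rho], u, axis=1)


def simulate_outcome(
    x_row: np.ndarray, beta: np.ndarray, rng: np.random.Generator
) -> int:
    """Bernoulli outcome with success probability expit(x . beta)."""
    x_row = np.asarray(x_row, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x_row.shape != beta.shape:
        raise ValueError("x_row and beta lengths differ")
    if not (np.isfinite(x_row).all() and np.isfinite(beta).all()):
        raise ValueError("non-finite inputs")
    p = expit(x_row @ beta)
    return int(rng.random() < p)


def generate_balanced(
    design: SimDesign,
    truth: TruthSpec,
    rng: np.random.Generator,
    batch_size: int = 256,
) -> LabeledData:
    """Fill the case/control quotas by per-row rejection sampling.

    Rows are generated (in batches, consumed strictly in generation order),
    each row's outcome is drawn, and the row is kept only when its class quota
    is still open; accepted rows are shuffled before return.
    """
    n_cases, n_controls = design.n_cases, design.n_controls
    kept_X: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    have = np.zeros(2, dtype=int)
    need = np.array([n_controls, n_cases])
    while (have < need).any():
        X = gen_covariates(batch_size, design, rng)
        p = expit(X @ truth.beta)
        y = (rng.random(batch_size) < p).astype(np.int8)
        # sequential acceptance: a row is kept iff its class quota is open
        # at the moment it is generated
        counts = have.copy()
        keep = np.zeros(batch_size, dtype=bool)
        for i in range(batch_size):
            c = y[i]
            if counts[c] < need[c]:
                counts[c] += 1
                keep[i] = True
            if (counts >= need).all():
                break
        kept_X.append(X[keep])
        kept_y.append(y[keep])
        have = counts
    X = np.concatenate(kept_X, axis=0)
    y = np.concatenate(kept_y, axis=0)
    perm = rng.permutation(X.shape[0])
    return LabeledData(X[perm], y[perm], variable_names(design.P))


def split_train_test(
    data: LabeledData,
    n_train: int,
    rng: np.random.Generator,
    stratified: bool = True,
) -> tuple[LabeledData, LabeledData]:
    """Random disjoint train/test partition, stratified by class by default."""
    n = data.n
    if not 0 < n_train < n:
        raise ValueError(f"n_train must lie in (0, {n}), got {n_train}")
    if stratified:
        frac = n_train / n
        train_idx: list[np.ndarray] = []
        # larger class rounds down first so totals hit n_train exactly
        classes = sorted((int(c) for c in np.unique(data.y)),
                         key=lambda c: -np.sum(data.y == c))
        taken = 0
        for pos, c in enumerate(classes):
            members = np.flatnonzero(data.y == c)
            k = int(round(frac * members.size))
            if pos == len(classes) - 1:
                k = n_train - taken
            k = min(max(k, 0), members.size)
            train_idx.append(rng.permutation(members)[:k])
            taken += k
        train = np.concatenate(train_idx)
    else:
        train = rng.permutation(n)[:n_train]
    train = np.sort(train)
    mask = np.zeros(n, dtype=bool)
    mask[train] = True
    return data.subset_rows(train), data.subset_rows(np.flatnonzero(~mask))


def write_labeled_data(data: LabeledData, path) -> None:
    """Serialize as TSV: sample_id, y, then one column per variable."""
    df = pd.DataFrame(data.X, columns=data.variable_names)
    df.insert(0, "y", data.y)
    df.insert(0, "sample_id", [f"s{i + 1}" for i in range(data.n)])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_labeled_data(path, y_col: str = "y") -> LabeledData:
    """Read a delimited matrix (TSV or CSV, sniffed from the header line)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if y_col not in df.columns:
        raise ValueError(f"outcome column {y_col!r} not found")
    y = df[y_col].to_numpy()
    drop = [y_col] + [c for c in ("sample_id",) if c in df.columns]
    feats = df.drop(columns=drop)
    return LabeledData(feats.to_numpy(dtype=float), y, list(feats.columns))
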