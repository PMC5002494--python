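"""Penalized logistic regression with LASSO, SCAD and MCP penalties.

The model minimises

    -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ] + sum_j P_lam(b_j),
    p_i = expit(b0 + x_i' b),

by iteratively reweighted least squares with cyclic coordinate descent on the
weighted quadratic surrogate. The intercept is never penalized; variables are
standardized internally and coefficients returned on the original scale. For
the folded-concave families (SCAD, MCP) the returned stationary point is
defined by warm-started descent along the regularization path from
``lam_max`` (where the solution is the exact null model).

The module exposes a statsmodels-flavoured surface: build a
:class:`PenalizedLogit` model from arrays, a DataFrame or a
:class:`~fdrsis.datagen.LabeledData`, then ``fit`` / ``fit_path`` /
``fit_cv``; each fit returns a :class:`PenalizedModel` results object with
``predict_proba`` and ``summary``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _solver
from .datagen import LabeledData

__all__ = [
    "PenaltySpec",
    "PenalizedModel",
    "CVResult",
    "PenalizedLogit",
    "penalty_value",
    "coordinate_minimizer",
    "fit_penalized_logistic",
    "lambda_path",
    "cv_select_lambda",
    "stratified_folds",
]

_FAMILY_CODE = {"lasso": _solver.LASSO, "scad": _solver.SCAD, "mcp": _solver.MCP}
DEFAULT_GAMMA = {"lasso": np.nan, "scad": 3.7, "mcp": 3.0}


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family with its tuning constants.

    gamma controls how fast the folded-concave penalties flatten: SCAD needs
    gamma > 2, MCP gamma > 1. Defaults are the conventional 3.7 (SCAD) and
    3.0 (MCP).
    """

    family: str
    lam: float
    gamma: float = np.nan

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_CODE:
            raise ValueError(f"unknown family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.family == "lasso":
            return
        g = self.gamma
        if np.isnan(g):
            object.__setattr__(self, "gamma", DEFAULT_GAMMA[self.family])
            return
        if self.family == "scad" and not g > 2:
            raise ValueError("SCAD requires gamma > 2")
        if self.family == "mcp" and not g > 1:
            raise ValueError("MCP requires gamma > 1")

    @property
    def code(self) -> int:
        return _FAMILY_CODE[self.family]


def penalty_value(spec: PenaltySpec, b) -> np.ndarray | float:
    """Penalty P_lam(b), vectorised over b.

    lasso: lam|b|; MCP: lam|b| - b^2/(2 gamma) up to |b| = gamma*lam then the
    constant gamma*lam^2/2; SCAD: lam|b| on [0, lam], the quadratic bridge
    (2 gamma lam |b| - b^2 - lam^2) / (2 (gamma - 1)) on (lam, gamma*lam],
    then the constant lam^2 (gamma + 1)/2.
    """
    b = np.asarray(b, dtype=float)
    lam, g = spec.lam, spec.gamma
    ab = np.abs(b)
    if spec.family == "lasso":
        out = lam * ab
    elif spec.family == "mcp":
        out = np.where(
            ab <= g * lam, lam * ab - b * b / (2 * g), 0.5 * g * lam * lam
        )
    else:
        out = np.where(
            ab <= lam,
            lam * ab,
            np.where(
                ab <= g * lam,
                (2 * g * lam * ab - b * b - lam * lam) / (2 * (g - 1)),
                0.5 * lam * lam * (g + 1),
            ),
        )
    return out if out.ndim else float(out)


def _soft(z: float, lam: float) -> float:
    return np.sign(z) * max(abs(z) - lam, 0.0)


def coordinate_minimizer(z: float, v: float, spec: PenaltySpec) -> float:
    """argmin over b of (v/2)(b - z/v)^2 + P_lam(b), for curvature v > 0.

    lasso: soft threshold S(z, lam)/v. MCP: firm threshold
    S(z, lam)/(v - 1/gamma) for |z| <= v*gamma*lam (valid when v > 1/gamma),
    else z/v; when v <= 1/gamma the interior branch is invalid and a
    grid-search minimiser is used with a warning. SCAD: three-piece rule
    matching the three penalty regions.
    """
    if v <= 0:
        raise ValueError("curvature v must be positive")
    lam, g = spec.lam, spec.gamma
    if spec.family == "lasso":
        return _soft(z, lam) / v
    if spec.family == "mcp":
        if abs(z) <= v * g * lam:
            if v <= 1.0 / g:
                warnings.warn(
                    "MCP coordinate update with v <= 1/gamma: surrogate is "
                    "non-convex on the interior region, falling back to "
                    "grid search",
                    RuntimeWarning,
                    stacklevel=2,
                )
                return _grid_minimizer(z, v, spec)
            return _soft(z, lam) / (v - 1.0 / g)
        return z / v
    # SCAD three-piece rule (exact piecewise minimisation)
    return float(_solver.cd_threshold(z, v, lam, g, spec.code))


def _grid_minimizer(z: float, v: float, spec: PenaltySpec) -> float:
    B = max(abs(z) / v, spec.gamma * spec.lam if spec.family != "lasso" else 0.0)
    B = 1.05 * B + 1e-8
    grid = np.linspace(-B, B, 200_001)
    h = 0.5 * v * grid**2 - z * grid + penalty_value(spec, grid)
    return float(grid[int(np.argmin(h))])


@dataclass
class _Standardization:
    center: np.ndarray
    scale: np.ndarray


def _standardize(X: np.ndarray) -> tuple[np.ndarray, _Standardization]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale <= 0
    scale = np.where(degenerate, 1.0, scale)
    return (X - center) / scale, _Standardization(center, scale)


@dataclass
class PenalizedModel:
    """Fitted penalized logistic model (results object).

    Coefficients are on the original covariate scale; ``standardization``
    records the per-variable center/scale the solver used internally.
    ``objective`` is the penalized objective at the solution on the
    standardized scale (the scale on which the penalty applies).
    """

    intercept: float
    beta: np.ndarray
    spec: PenaltySpec
    n_iter: int
    converged: bool
    objective: float
    standardization: _Standardization
    variable_names: list[str] = field(default_factory=list)
    cv: "CVResult | None" = None

    @property
    def support(self) -> np.ndarray:
        """Indices of nonzero coefficients, ascending."""
        return np.flatnonzero(self.beta)

    @property
    def model_size(self) -> int:
        return int(self.support.size)

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.beta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.predict_linear(X))

    def coef_table(self) -> pd.DataFrame:
        idx = self.support
        names = (
            [self.variable_names[j] for j in idx]
            if self.variable_names
            else [f"x{j}" for j in idx]
        )
        return pd.DataFrame(
            {"variable": names, "index": idx, "coef": self.beta[idx]}
        )

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Penalized logistic regression",
            "=" * 45,
            f"family:        {spec.family}",
            f"lambda:        {spec.lam:.6g}"
            + (f"   gamma: {spec.gamma:g}" if spec.family != "lasso" else ""),
            f"n variables:   {self.beta.size}",
            f"model size:    {self.model_size}",
            f"converged:     {self.converged} ({self.n_iter} outer iterations)",
            f"objective:     {self.objective:.6f}",
            "-" * 45,
            f"intercept      {self.intercept:+.6f}",
        ]
        for _, row in self.coef_table().iterrows():
            lines.append(f"{row['variable']:<14s} {row['coef']:+.6f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        idx = self.support
        names = (
            [self.variable_names[j] for j in idx]
            if self.variable_names
            else [f"x{j}" for j in idx]
        )
        return {
            "family": self.spec.family,
            "lam": self.spec.lam,
            "gamma": None if self.spec.family == "lasso" else self.spec.gamma,
            "intercept": self.intercept,
            "coefficients": {n: float(self.beta[j]) for n, j in zip(names, idx)},
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "objective": float(self.objective),
        }


@dataclass
class CVResult:
    """Cross-validation trace over a shared decreasing lambda grid."""

    lam_grid: np.ndarray
    cv_loss: np.ndarray
    lam_chosen: float
    fold_assignment: np.ndarray


class PenalizedLogit:
    """Penalized logistic regression model (statsmodels-style endog/exog)."""

    def __init__(self, endog, exog, variable_names: list[str] | None = None):
        self.y = np.asarray(endog)
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("exog must be (n, p) matching endog")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("endog must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("endog must contain both classes")
        self.y = self.y.astype(float)
        self.variable_names = list(variable_names or [])
        self._Xs, self._std = _standardize(self.X)

    @classmethod
    def from_labeled_data(cls, data: LabeledData) -> "PenalizedLogit":
        return cls(data.y, data.X, data.variable_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y_col: str = "y") -> "PenalizedLogit":
        y = df[y_col].to_numpy()
        feats = df.drop(columns=[y_col])
        return cls(y, feats.to_numpy(dtype=float), list(feats.columns))

    # -- path machinery ----------------------------------------------------

    @property
    def lam_max(self) -> float:
        """Smallest lambda at which every slope is exactly zero."""
        ybar = self.y.mean()
        score = self._Xs.T @ (self.y - ybar) / self.y.size
        lam = float(np.max(np.abs(score)))
        if lam <= 0:
            raise ValueError("degenerate design: all columns constant")
        return lam

    def lambda_grid(self, n_lambda: int = 40, ratio: float = 0.02) -> np.ndarray:
        if n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < ratio < 1:
            raise ValueError("ratio must lie in (0, 1)")
        lmax = self.lam_max
        return np.geomspace(lmax, ratio * lmax, n_lambda)

    def _solve_path(self, lambdas, spec_family, gamma, tol, max_outer):
        code = _FAMILY_CODE[spec_family]
        g = DEFAULT_GAMMA[spec_family] if np.isnan(gamma) else gamma
        if spec_family == "lasso":
            g = 1.0  # unused by the kernel
        return _solver.cd_path(
            self._Xs,
            self.y,
            np.asarray(lambdas, dtype=float),
            float(g),
            code,
            tol,
            max_outer,
            200,
        )

    def _warm_grid(self, lam: float) -> np.ndarray:
        """Internal warm-start path from lam_max down to the target lam."""
        lmax = self.lam_max
        if lam >= lmax:
            return np.array([lam])
        lo = max(lam, 1e-3 * lmax)
        grid = np.geomspace(lmax, lo, 12)
        if lam < lo:
            grid = np.append(grid, lam)
        elif grid[-1] != lam:
            grid[-1] = lam
        return grid

    def _unstandardize(self, b0: float, beta_std: np.ndarray):
        beta = beta_std / self._std.scale
        intercept = b0 - float(np.dot(beta_std, self._std.center / self._std.scale))
        return intercept, beta

    def fit(
        self,
        spec: PenaltySpec,
        tol: float = 1e-7,
        max_outer: int = 100,
        warm_path: bool = True,
    ) -> PenalizedModel:
        """Fit at a single lambda (warm-started from lam_max by default)."""
        grid = self._warm_grid(spec.lam) if warm_path else np.array([spec.lam])
        B0, B, NIT, CONV, OBJ = self._solve_path(
            grid, spec.family, spec.gamma, tol, max_outer
        )
        if not CONV[-1]:
            warnings.warn(
                f"penalized fit did not converge in {max_outer} outer "
                "iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        intercept, beta = self._unstandardize(B0[-1], B[-1])
        return PenalizedModel(
            intercept=intercept,
            beta=beta,
            spec=spec,
            n_iter=int(NIT.sum()),
            converged=bool(CONV[-1]),
            objective=float(OBJ[-1]),
            standardization=self._std,
            variable_names=self.variable_names,
        )

    def fit_path(
        self,
        family: str = "lasso",
        gamma: float = np.nan,
        n_lambda: int = 40,
        ratio: float = 0.02,
        lambdas: np.ndarray | None = None,
        tol: float = 1e-7,
        max_outer: int = 100,
    ) -> list[PenalizedModel]:
        grid = self.lambda_grid(n_lambda, ratio) if lambdas is None else lambdas
        B0, B, NIT, CONV, OBJ = self._solve_path(grid, family, gamma, tol, max_outer)
        models = []
        for k, lam in enumerate(grid):
            intercept, beta = self._unstandardize(B0[k], B[k])
            models.append(
                PenalizedModel(
                    intercept=intercept,
                    beta=beta,
                    spec=PenaltySpec(family, float(lam), gamma),
                    n_iter=int(NIT[k]),
                    converged=bool(CONV[k]),
                    objective=float(OBJ[k]),
                    standardization=self._std,
                    variable_names=self.variable_names,
                )
            )
        return models

    def fit_cv(
        self,
        family: str = "lasso",
        gamma: float = np.nan,
        n_folds: int = 10,
        rng: np.random.Generator | None = None,
        n_lambda: int = 40,
        ratio: float = 0.02,
        loss: str = "deviance",
        tol: float = 1e-7,
        max_outer: int = 100,
    ) -> PenalizedModel:
        """Tune lambda by stratified K-fold CV, then refit on all data."""
        cvres = self.cv_select(
            family, gamma, n_folds, rng, n_lambda, ratio, loss, tol, max_outer
        )
        model = self.fit(
            PenaltySpec(family, cvres.lam_chosen, gamma), tol=tol, max_outer=max_outer
        )
        model.cv = cvres
        return model

    def cv_select(
        self,
        family: str = "lasso",
        gamma: float = np.nan,
        n_folds: int = 10,
        rng: np.random.Generator | None = None,
        n_lambda: int = 40,
        ratio: float = 0.02,
        loss: str = "deviance",
        tol: float = 1e-7,
        max_outer: int = 100,
    ) -> CVResult:
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if loss not in ("deviance", "misclass", "auroc"):
            raise ValueError("loss must be deviance, misclass or auroc")
        rng = np.random.default_rng(0) if rng is None else rng
        folds = stratified_folds(self.y, n_folds, rng)
        grid = self.lambda_grid(n_lambda, ratio)
        n = self.y.size
        loss_sum = np.zeros(grid.size)
        for k in range(n_folds):
            test_mask = folds == k
            tr = PenalizedLogit(
                self.y[~test_mask], self.X[~test_mask], self.variable_names
            )
            B0, B, _, _, _ = tr._solve_path(grid, family, gamma, tol, max_outer)
            Xte, yte = self.X[test_mask], self.y[test_mask]
            for li in range(grid.size):
                intercept, beta = tr._unstandardize(B0[li], B[li])
                p = expit(intercept + Xte @ beta)
                p = np.clip(p, 1e-10, 1 - 1e-10)
                if loss == "deviance":
                    loss_sum[li] += -2.0 * float(
                        np.sum(yte * np.log(p) + (1 - yte) * np.log(1 - p))
                    )
                elif loss == "misclass":
                    loss_sum[li] += float(np.sum((p >= 0.5) != (yte == 1)))
                else:
                    from .metrics import auroc

                    loss_sum[li] += -auroc(p, yte) * yte.size
        cv_loss = loss_sum / n
        best = int(np.argmin(cv_loss))  # first minimum = larger lambda on ties
        return CVResult(
            lam_grid=grid,
            cv_loss=cv_loss,
            lam_chosen=float(grid[best]),
            fold_assignment=folds,
        )


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Class-stratified fold labels in {0..n_folds-1}; every fold must end up
    with both classes."""
    y = np.asarray(y)
    folds = np.empty(y.size, dtype=np.intp)
    for c in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == c))
        if members.size < n_folds:
            raise ValueError(
                f"class {c} has fewer members ({members.size}) than folds "
                f"({n_folds}); cannot stratify"
            )
        folds[members] = np.arange(members.size) % n_folds
    return folds


# -- functional wrappers (module-level operation surface) -------------------


def fit_penalized_logistic(
    data: LabeledData, spec: PenaltySpec, **opts
) -> PenalizedModel:
    return PenalizedLogit.from_labeled_data(data).fit(spec, **opts)


def lambda_path(
    data: LabeledData,
    family: str = "lasso",
    gamma: float = np.nan,
    n_lambda: int = 40,
    ratio: float = 0.02,
) -> np.ndarray:
    """Decreasing log-spaced lambda grid from lam_max to ratio*lam_max."""
    del family, gamma  # lam_max is family-independent (threshold at zero)
    return PenalizedLogit.from_labeled_data(data).lambda_grid(n_lambda, ratio)


def cv_select_lambda(
    data: LabeledData,
    family: str = "lasso",
    gamma: float = np.nan,
    n_folds: int = 10,
    rng: np.random.Generator | None = None,
    **opts,
) -> CVResult:
    return PenalizedLogit.from_labeled_data(data).cv_select(
        family, gamma, n_folds, rng, **opts
    )
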