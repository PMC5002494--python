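"""Iterative sure independence screening (ISIS) for logistic outcomes.

The loop alternates two moves on a candidate pool: rank candidates by the
maximized log-likelihood of a logistic model conditional on the variables
already kept, retain the top d = floor(N / (4 ln N)); then run a penalized
logistic fit (CV-tuned lambda) on the retained union and keep its support.
Iteration stops when the kept set reaches size d, repeats itself, or the
iteration cap is hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .datagen import LabeledData
from .penalized import PenalizedLogit, PenaltySpec
from .screening import COEF_CLAMP, marginal_logistic_stats

__all__ = [
    "ISISConfig",
    "ISISResult",
    "compute_d",
    "conditional_rank",
    "isis",
]


def compute_d(N: int) -> int:
    """Screening size d = floor(N / (4 ln N)), clamped below at 1."""
    if N < 2:
        raise ValueError("N must be >= 2")
    return max(1, int(np.floor(N / (4.0 * np.log(N)))))


@dataclass(frozen=True)
class ISISConfig:
    """Tuning knobs of the ISIS loop.

    d defaults to floor(N / (4 ln N)); the penalized family used inside the
    iterations is the same as the final selection family; lambda in each
    inner fit is tuned by stratified cv_folds-fold CV unless ``fixed_lam``
    pins it.
    """

    d: int | None = None
    max_iter: int = 10
    family: str = "lasso"
    gamma: float = np.nan
    cv_folds: int = 10
    n_lambda: int = 40
    lam_ratio: float = 0.02
    fixed_lam: float | None = None
    conditional_mode: str = "joint"  # or "offset"

    def __post_init__(self) -> None:
        if self.d is not None and self.d < 1:
            raise ValueError("d must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.conditional_mode not in ("joint", "offset"):
            raise ValueError("conditional_mode must be 'joint' or 'offset'")


@dataclass
class ISISResult:
    """Final kept set with the per-iteration trace."""

    final_set: np.ndarray
    history: list[dict] = field(default_factory=list)
    n_iter: int = 0
    stop_reason: str = ""  # reached_d | fixed_point | max_iter


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 25,
    clamp: float = COEF_CLAMP,
) -> tuple[np.ndarray, float]:
    """Small dense Newton fit of intercept + X; returns (coefs, loglik).

    Coefficients are clamped at +/-clamp so separated designs stay finite
    (same policy as the marginal screens).
    """
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    if start is None:
        ybar = y.mean()
        coef = np.zeros(p + 1)
        coef[0] = np.log(ybar / (1.0 - ybar))
    else:
        coef = start.copy()
    for _ in range(max_iter):
        eta = Z @ coef
        prob = expit(eta)
        w = prob * (1.0 - prob)
        g = Z.T @ (y - prob)
        H = (Z * w[:, None]).T @ Z
        H.flat[:: p + 2] += 1e-9  # tiny ridge for near-singular designs
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            break
        coef += step
        hit = np.abs(coef) > clamp
        if hit.any():
            coef[hit] = np.sign(coef[hit]) * clamp
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = Z @ coef
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return coef, ll


def conditional_rank(
    data: LabeledData,
    conditioned: np.ndarray,
    candidates: np.ndarray,
    mode: str = "joint",
) -> np.ndarray:
    """Rank candidates by conditional model log-likelihood, descending.

    For each candidate j the logistic model on conditioned + {j} is
    maximized; in "joint" mode the conditioned coefficients are re-estimated
    with the candidate, in "offset" mode they are frozen at the
    conditioned-only fit and enter as a fixed offset. Ties are broken by
    ascending variable index. With an empty conditioned set this reduces to
    the marginal likelihood ranking.
    """
    conditioned = np.asarray(conditioned, dtype=np.intp)
    candidates = np.asarray(candidates, dtype=np.intp)
    if np.intersect1d(conditioned, candidates).size:
        raise ValueError("conditioned and candidate sets must be disjoint")
    if candidates.size == 0:
        return candidates
    y = data.y.astype(float)
    if conditioned.size == 0:
        stats = marginal_logistic_stats(
            LabeledData(
                data.X[:, candidates],
                data.y,
                [data.variable_names[j] for j in candidates],
            )
        )
        ll = stats.loglik
    else:
        Xc = data.X[:, conditioned]
        base_coef, _ = _newton_logistic(Xc, y)
        ll = np.empty(candidates.size)
        if mode == "joint":
            start = np.append(base_coef, 0.0)
            for i, j in enumerate(candidates):
                _, ll[i] = _newton_logistic(
                    np.column_stack([Xc, data.X[:, j]]), y, start=start
                )
        elif mode == "offset":
            offset = base_coef[0] + Xc @ base_coef[1:]
            for i, j in enumerate(candidates):
                ll[i] = _offset_marginal_loglik(data.X[:, j], y, offset)
        else:
            raise ValueError("mode must be 'joint' or 'offset'")
    order = np.lexsort((candidates, -ll))
    return candidates[order]


def _offset_marginal_loglik(x, y, offset, max_iter=25):
    """Single-slope logistic fit on top of a frozen linear offset."""
    b = 0.0
    a = 0.0
    for _ in range(max_iter):
        eta = offset + a + b * x
        prob = expit(eta)
        w = prob * (1 - prob)
        g = np.array([np.sum(y - prob), np.sum(x * (y - prob))])
        H = np.array(
            [
                [np.sum(w), np.sum(w * x)],
                [np.sum(w * x), np.sum(w * x * x) + 1e-9],
            ]
        )
        da, db = np.linalg.solve(H, g)
        a += da
        b += db
        b = float(np.clip(b, -COEF_CLAMP, COEF_CLAMP))
        if max(abs(da), abs(db)) < 1e-9:
            break
    eta = offset + a + b * x
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _penalized_support(
    data: LabeledData,
    working: np.ndarray,
    config: ISISConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """CV-tuned penalized fit on the working columns; returns (support indices
    in original coordinates, standardized |coef| for tie ranking)."""
    model_obj = PenalizedLogit(
        data.y,
        data.X[:, working],
        [data.variable_names[j] for j in working],
    )
    if config.fixed_lam is not None:
        fit = model_obj.fit(
            PenaltySpec(config.family, config.fixed_lam, config.gamma)
        )
    else:
        fit = model_obj.fit_cv(
            config.family,
            config.gamma,
            n_folds=config.cv_folds,
            rng=rng,
            n_lambda=config.n_lambda,
            ratio=config.lam_ratio,
        )
    std_mag = np.abs(fit.beta * fit.standardization.scale)
    sup_local = fit.support
    return working[sup_local], std_mag[sup_local]


def isis(
    data: LabeledData,
    candidates: np.ndarray,
    config: ISISConfig,
    rng: np.random.Generator,
) -> ISISResult:
    """Run the ISIS loop on a candidate variable pool.

    Step 1 ranks candidates marginally and keeps the top d; step 2 takes the
    support of a penalized fit on them; steps 3-4 re-rank the remaining
    candidates conditional on the current kept set, keep the top d, and
    refit on the union; repeated until the kept set has size d, is unchanged,
    or ``max_iter`` is reached. If a penalized fit returns more than d
    variables, the d largest standardized coefficients are kept and the loop
    stops (the size-d stopping rule).
    """
    candidates = np.unique(np.asarray(candidates, dtype=np.intp))
    if candidates.size == 0:
        raise ValueError("candidate set must be nonempty")
    N = data.n
    d = config.d if config.d is not None else compute_d(N)

    history: list[dict] = []

    def _cap(sup: np.ndarray, mag: np.ndarray) -> tuple[np.ndarray, bool]:
        if sup.size <= d:
            return np.sort(sup), False
        keep = np.lexsort((sup, -mag))[:d]
        return np.sort(sup[keep]), True

    # step (1)-(2): marginal ranking, first penalized fit
    ranked = conditional_rank(data, np.empty(0, np.intp), candidates,
                              config.conditional_mode)
    I_l = np.sort(ranked[:d])
    sup, mag = _penalized_support(data, I_l, config, rng)
    M_prev, capped = _cap(sup, mag)
    history.append({"I": I_l, "M": M_prev})

    stop_reason = "max_iter"
    n_iter = 1
    if capped or M_prev.size == d:
        stop_reason = "reached_d"
    else:
        for _ in range(1, config.max_iter):
            n_iter += 1
            remaining = np.setdiff1d(candidates, M_prev)
            ranked = conditional_rank(data, M_prev, remaining,
                                      config.conditional_mode)
            I_l = np.sort(ranked[:d])
            working = np.union1d(I_l, M_prev)
            sup, mag = _penalized_support(data, working, config, rng)
            M_new, capped = _cap(sup, mag)
            history.append({"I": I_l, "M": M_new})
            if capped or M_new.size == d:
                M_prev = M_new
                stop_reason = "reached_d"
                break
            if np.array_equal(M_new, M_prev):
                stop_reason = "fixed_point"
                M_prev = M_new
                break
            M_prev = M_new

    if stop_reason == "max_iter":
        warnings.warn(
            f"ISIS hit max_iter={config.max_iter} without a fixed point",
            RuntimeWarning,
            stacklevel=2,
        )
    return ISISResult(
        final_set=M_prev,
        history=history,
        n_iter=n_iter,
        stop_reason=stop_reason,
    )
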