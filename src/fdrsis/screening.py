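"""Marginal logistic screening statistics and dimension-reduction rules.

Two screens are provided: Benjamini-Hochberg step-up selection at FDR level q
on per-variable likelihood-ratio p-values, and plain top-K filtering on the
smallest unadjusted p-values (the "random filter" reference screen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .datagen import LabeledData

__all__ = [
    "MarginalStats",
    "ScreenResult",
    "marginal_logistic_stats",
    "bh_select",
    "random_filter",
]

#: coefficient magnitude clamp for (near-)separated marginal fits
COEF_CLAMP = 30.0
#: Newton iteration cap for marginal fits
MAX_NEWTON = 25


@dataclass(frozen=True)
class MarginalStats:
    """Per-variable single-covariate logistic regression summaries."""

    p_values: np.ndarray  # LRT (or Wald) p-value per variable
    loglik: np.ndarray  # maximized marginal log-likelihood per variable
    statistic: np.ndarray  # test statistic per variable

    @property
    def P(self) -> int:
        return self.p_values.size


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a screening rule: the surviving variable index set."""

    method: str  # "fdr" | "topk"
    selected: np.ndarray  # 0-based indices, ordered
    q: float | None = None
    K: int | None = None
    k_hat: int = 0
    adjusted_p: np.ndarray | None = None


def _null_loglik(y: np.ndarray) -> float:
    n = y.size
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return 0.0
    return n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))


def marginal_logistic_stats(
    data: LabeledData, statistic: str = "lrt"
) -> MarginalStats:
    """Fit intercept + x_j logistic regression for every variable j.

    All P two-parameter Newton iterations run simultaneously as vectorised
    array operations; coefficients are clamped at +/-30 so separated fits
    cannot diverge. The reported p-value is the likelihood-ratio test against
    the intercept-only model (chi-square, 1 df) by default, or a Wald test
    with ``statistic="wald"``.

    Notes
    -----
    A constant column carries no information: its slope stays 0 and the
    p-value is 1.
    """
    if statistic not in ("lrt", "wald"):
        raise ValueError("statistic must be 'lrt' or 'wald'")
    X = data.X
    y = data.y.astype(float)
    n, P = X.shape
    if y.min() == y.max():
        raise ValueError("y must contain both classes")

    ll0 = _null_loglik(data.y)
    ybar = y.mean()
    a = np.full(P, np.log(ybar / (1 - ybar)))  # intercepts
    b = np.zeros(P)  # slopes
    yc = y[:, None]
    clamped = np.zeros(P, dtype=bool)
    for _ in range(MAX_NEWTON):
        eta = a[None, :] + X * b[None, :]
        p = expit(eta)
        w = p * (1.0 - p)
        r = yc - p
        g0 = r.sum(axis=0)
        g1 = (X * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X * X).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(det > 1e-12, det, np.inf)  # constant column -> no step
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        a += da
        b += db
        over = np.abs(b) > COEF_CLAMP
        if over.any():
            clamped |= over
            b[over] = np.sign(b[over]) * COEF_CLAMP
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < 1e-9:
            break
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} marginal fit(s) hit the coefficient clamp "
            f"(+/-{COEF_CLAMP:g}); likely perfect separation",
            RuntimeWarning,
            stacklevel=2,
        )

    eta = a[None, :] + X * b[None, :]
    ll = (yc * eta - np.logaddexp(0.0, eta)).sum(axis=0)

    if statistic == "lrt":
        stat = np.maximum(2.0 * (ll - ll0), 0.0)
    else:
        p_ = expit(eta)
        w = p_ * (1.0 - p_)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X * X).sum(axis=0)
        var_b = h00 / np.maximum(h00 * h11 - h01 * h01, 1e-300)
        stat = b * b / np.maximum(var_b, 1e-300)
    pvals = stats.chi2.sf(stat, df=1)
    pvals = np.where(stat <= 0.0, 1.0, pvals)
    return MarginalStats(p_values=pvals, loglik=ll, statistic=stat)


def bh_select(
    p_values: np.ndarray, q: float, strict_gt1: bool = False
) -> ScreenResult:
    """Benjamini-Hochberg step-up selection at FDR level q.

    k_hat is the largest rank k with p_(k) <= k*q/m (0 if none); the selected
    set holds the k_hat smallest p-values, bit-identical ties broken by
    ascending variable index. ``strict_gt1`` reproduces a stricter variant
    that rejects only when k_hat > 1.
    """
    p = np.asarray(p_values, dtype=float)
    if not ((p >= 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    m = p.size
    order = np.lexsort((np.arange(m), p))  # by p, ties by index
    p_sorted = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    hits = np.flatnonzero(p_sorted <= thresh)
    k_hat = int(hits[-1] + 1) if hits.size else 0
    if strict_gt1 and k_hat == 1:
        k_hat = 0
    selected = np.sort(order[:k_hat])
    adj = multipletests(p, alpha=q, method="fdr_bh")[1] if m else np.empty(0)
    return ScreenResult(
        method="fdr", selected=selected, q=q, k_hat=k_hat, adjusted_p=adj
    )


def random_filter(p_values: np.ndarray, K: int) -> ScreenResult:
    """Keep the K variables with smallest unadjusted p-values (RF_K screen).

    Ties broken by lowest index; K >= P keeps everything.
    """
    p = np.asarray(p_values, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    m = p.size
    order = np.lexsort((np.arange(m), p))
    selected = np.sort(order[: min(K, m)])
    return ScreenResult(method="topk", selected=selected, K=K)
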