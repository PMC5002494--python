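"""Selection and prediction performance metrics.

True/false positive rates come from the 2x2 cross of the selected variable
set against the true support; the false discovery proportion is V/R (0 when
nothing is selected), whose average across simulation replicates estimates
the FDR E[V/R | R > 0]. AUROC is computed in its Mann-Whitney form:
the probability that a random case outscores a random control, ties counted
one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datagen import TruthSpec

__all__ = ["SelectionMetrics", "auroc", "selection_metrics"]


@dataclass(frozen=True)
class SelectionMetrics:
    tp_rate: float
    fp_rate: float
    fdp: float
    n_false_pos: int
    model_size: int
    n_screened_true: int


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    ranks = rankdata(scores)  # average ranks handle ties at 1/2
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def selection_metrics(
    selected: np.ndarray,
    truth: TruthSpec,
    P: int,
    screened: np.ndarray | None = None,
) -> SelectionMetrics:
    """Cross the selected set against the true support over all P variables."""
    selected = np.asarray(selected, dtype=np.intp)
    if selected.size and (selected.min() < 0 or selected.max() >= P):
        raise ValueError("selected indices out of range")
    support = set(int(j) for j in truth.support)
    sel = set(int(j) for j in selected)
    tp = len(sel & support)
    fp = len(sel - support)
    fn = len(support - sel)
    tn = P - tp - fp - fn
    n_pos = tp + fn
    n_neg = tn + fp
    r = len(sel)
    scr = set(int(j) for j in np.asarray(screened)) if screened is not None else set()
    return SelectionMetrics(
        tp_rate=tp / n_pos if n_pos else 0.0,
        fp_rate=fp / n_neg if n_neg else 0.0,
        fdp=fp / r if r else 0.0,
        n_false_pos=fp,
        model_size=r,
        n_screened_true=len(scr & support),
    )
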