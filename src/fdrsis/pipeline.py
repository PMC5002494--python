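"""End-to-end selection pipeline and the replicated simulation study.

A single pipeline run is: marginal logistic statistics on the training split
-> dimension-reduction screen (BH step-up at level q, or top-K filtering) ->
ISIS on the surviving set -> final CV-tuned penalized fit restricted to the
ISIS output -> AUROC of the fitted probabilities on the held-out test split.
The study runner repeats this over replicated synthetic datasets, pairing
every (screen, penalty family) scenario on the same data within a replicate,
and aggregates selection/prediction metrics with standard errors plus
per-true-variable selection frequencies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datagen import (
    LabeledData,
    SimDesign,
    TruthSpec,
    draw_true_beta,
    generate_balanced,
    split_train_test,
)
from .isis import ISISConfig, isis
from .metrics import SelectionMetrics, auroc, selection_metrics
from .penalized import PenalizedLogit, PenalizedModel
from .screening import MarginalStats, ScreenResult, bh_select, marginal_logistic_stats, random_filter

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateResult",
    "StudyTable",
    "run_pipeline",
    "run_simulation_study",
    "write_study_table",
    "read_study_table",
    "STUDY_TABLE_COLUMNS",
]

#: aggregate table schema (means and standard errors per scenario)
STUDY_TABLE_COLUMNS = [
    "screening",
    "method",
    "TP",
    "TP_se",
    "FP",
    "FP_se",
    "FDR",
    "FDR_se",
    "ANFP",
    "ANFP_se",
    "Size",
    "Size_se",
    "AUROC",
    "AUROC_se",
    "n_filter",
    "n_filter_se",
]


@dataclass
class ReplicateResult:
    """One pipeline run on one simulated dataset."""

    metrics: SelectionMetrics
    auroc: float
    selected_names: list[str]
    screening: str
    family: str
    seed: int
    model: PenalizedModel | None = None
    screened: np.ndarray | None = None


def _screen_tag(screen_spec: tuple) -> str:
    method, value = screen_spec
    if method == "fdr":
        return f"fdr_{value:g}"
    if method == "topk":
        return f"topk_{int(value)}"
    raise ValueError(f"unknown screening method {method!r}")


def apply_screen(stats: MarginalStats, screen_spec: tuple) -> ScreenResult:
    method, value = screen_spec
    if method == "fdr":
        return bh_select(stats.p_values, q=value)
    if method == "topk":
        return random_filter(stats.p_values, K=int(value))
    raise ValueError(f"unknown screening method {method!r}")


def run_pipeline(
    train: LabeledData,
    test: LabeledData,
    screen_spec: tuple,
    config: ISISConfig,
    rng: np.random.Generator,
    truth: TruthSpec | None = None,
    stats: MarginalStats | None = None,
    screen: ScreenResult | None = None,
    seed: int = -1,
) -> ReplicateResult:
    """Screen -> ISIS -> final CV-tuned penalized fit -> test-set AUROC.

    ``stats``/``screen`` may be passed precomputed so several scenarios can
    share one marginal pass on the same training data. With an empty screen
    the final model is intercept-only and the AUROC is 0.5 by construction.
    """
    if train.variable_names != test.variable_names:
        raise ValueError("train and test must share variables")
    if stats is None:
        stats = marginal_logistic_stats(train)
    if screen is None:
        screen = apply_screen(stats, screen_spec)
    screened = screen.selected

    if screened.size == 0:
        selected = np.empty(0, dtype=np.intp)
        model = None
        auc = 0.5
    else:
        isis_res = isis(train, screened, config, rng)
        final_set = isis_res.final_set
        if final_set.size == 0:
            selected = final_set
            model = None
            auc = 0.5
        else:
            fitter = PenalizedLogit(
                train.y,
                train.X[:, final_set],
                [train.variable_names[j] for j in final_set],
            )
            model = fitter.fit_cv(
                config.family,
                config.gamma,
                n_folds=config.cv_folds,
                rng=rng,
                n_lambda=config.n_lambda,
                ratio=config.lam_ratio,
            )
            selected = final_set[model.support]
            auc = auroc(model.predict_proba(test.X[:, final_set]), test.y)

    if truth is None:
        truth = TruthSpec(
            support=np.empty(0, np.intp), beta=np.zeros(train.P)
        )
    mets = selection_metrics(selected, truth, train.P, screened=screened)
    return ReplicateResult(
        metrics=mets,
        auroc=float(auc),
        selected_names=[train.variable_names[j] for j in selected],
        screening=_screen_tag(screen_spec),
        family=config.family,
        seed=seed,
    )


@dataclass
class StudyTable:
    """Aggregated simulation study: the per-scenario summary table, the
    per-replicate rows behind it, and selection-frequency tallies for the
    true variables."""

    table: pd.DataFrame  # columns STUDY_TABLE_COLUMNS
    replicates: list[dict]
    selection_frequency: pd.DataFrame  # scenario x true-variable counts
    n_reps: int

    def __eq__(self, other) -> bool:  # round-trip identity for testing
        if not isinstance(other, StudyTable):
            return NotImplemented
        return (
            self.n_reps == other.n_reps
            and self.replicates == other.replicates
            and self.table.round(12).equals(other.table.round(12))
            and self.selection_frequency.equals(other.selection_frequency)
        )


def _aggregate(replicates: list[dict], truth_names: list[str], n_reps: int) -> StudyTable:
    rows = []
    ok = [r for r in replicates if r.get("failed") is not True]
    df = pd.DataFrame(ok)
    freq_rows = {}
    for (tag, fam), grp in df.groupby(["screening", "family"], sort=False):
        def ms(col):
            vals = grp[col].to_numpy(dtype=float)
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            return float(vals.mean()), float(se)

        tp, tp_se = ms("tp_rate")
        fp, fp_se = ms("fp_rate")
        fdr, fdr_se = ms("fdp")
        anfp, anfp_se = ms("n_false_pos")
        size, size_se = ms("model_size")
        auc, auc_se = ms("auroc")
        nf, nf_se = ms("n_screened_true")
        rows.append(
            dict(
                zip(
                    STUDY_TABLE_COLUMNS,
                    [tag, fam, tp, tp_se, fp, fp_se, fdr, fdr_se, anfp,
                     anfp_se, size, size_se, auc, auc_se, nf, nf_se],
                )
            )
        )
        counts = {name: 0 for name in truth_names}
        for sel in grp["selected_names"]:
            for name in sel:
                if name in counts:
                    counts[name] += 1
        freq_rows[f"{tag}:{fam}"] = counts
    table = pd.DataFrame(rows, columns=STUDY_TABLE_COLUMNS)
    freq = pd.DataFrame(freq_rows).T
    freq.index.name = "scenario"
    if truth_names:
        freq = freq[truth_names]
    return StudyTable(
        table=table,
        replicates=replicates,
        selection_frequency=freq,
        n_reps=n_reps,
    )


def run_simulation_study(
    design: SimDesign,
    scenarios: list[tuple[tuple, str]],
    n_reps: int,
    master_seed: int,
    isis_config: ISISConfig | None = None,
    train_fraction: float = 600.0 / 900.0,
    stratified_split: bool = True,
) -> StudyTable:
    """Replicated study over (screen_spec, family) scenarios.

    Every scenario within a replicate sees the same generated data and the
    same train/test split, so method contrasts are paired. Replicate r uses
    a child seed deterministically derived from ``master_seed``. A failed
    replicate-scenario is logged and recorded with ``failed=True``, never
    silently dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = isis_config or ISISConfig()
    replicates: list[dict] = []
    n_total = design.n_cases + design.n_controls
    n_train = int(round(train_fraction * n_total))
    truth_names = None

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_reps)
    for r in range(n_reps):
        rep_ss = children[r]
        rng = np.random.default_rng(rep_ss)
        truth = draw_true_beta(design, rng)
        data = generate_balanced(design, truth, rng)
        if truth_names is None:
            truth_names = [data.variable_names[j] for j in truth.support]
        train, test = split_train_test(
            data, n_train, rng, stratified=stratified_split
        )
        stats = marginal_logistic_stats(train)
        screens = {}
        for spec_pair in scenarios:
            screen_spec = spec_pair[0]
            tag = _screen_tag(screen_spec)
            if tag not in screens:
                screens[tag] = apply_screen(stats, screen_spec)
        scen_seeds = rep_ss.spawn(len(scenarios))
        for s_idx, (screen_spec, family) in enumerate(scenarios):
            cfg = replace(base, family=family)
            tag = _screen_tag(screen_spec)
            scen_rng = np.random.default_rng(scen_seeds[s_idx])
            try:
                res = run_pipeline(
                    train,
                    test,
                    screen_spec,
                    cfg,
                    scen_rng,
                    truth=truth,
                    stats=stats,
                    screen=screens[tag],
                    seed=r,
                )
                replicates.append(
                    {
                        "replicate": r,
                        "screening": res.screening,
                        "family": res.family,
                        "tp_rate": res.metrics.tp_rate,
                        "fp_rate": res.metrics.fp_rate,
                        "fdp": res.metrics.fdp,
                        "n_false_pos": res.metrics.n_false_pos,
                        "model_size": res.metrics.model_size,
                        "n_screened_true": res.metrics.n_screened_true,
                        "auroc": res.auroc,
                        "selected_names": res.selected_names,
                    }
                )
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                logger.exception(
                    "replicate %d scenario %s:%s failed", r, tag, family
                )
                replicates.append(
                    {
                        "replicate": r,
                        "screening": tag,
                        "family": family,
                        "failed": True,
                        "error": repr(exc),
                    }
                )
    return _aggregate(replicates, truth_names or [], n_reps)


def write_study_table(table: StudyTable, path) -> None:
    """TSV of the aggregate table plus a ``<path>.json`` sidecar holding the
    per-replicate rows and selection frequencies."""
    table.table.to_csv(path, sep="\t", index=False)
    sidecar = {
        "n_reps": table.n_reps,
        "replicates": table.replicates,
        "selection_frequency": {
            scen: {k: int(v) for k, v in row.items()}
            for scen, row in table.selection_frequency.iterrows()
        },
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_study_table(path) -> StudyTable:
    df = pd.read_csv(path, sep="\t")
    with open(f"{path}.json") as fh:
        sidecar = json.load(fh)
    freq = pd.DataFrame(sidecar["selection_frequency"]).T
    freq.index.name = "scenario"
    return StudyTable(
        table=df,
        replicates=sidecar["replicates"],
        selection_frequency=freq,
        n_reps=sidecar["n_reps"],
    )
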