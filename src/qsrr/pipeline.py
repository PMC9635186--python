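"""End-to-end orchestration of the retention-modeling workflow.

Stages: descriptor filtering -> linearity screen -> firefly descriptor
selection -> final SVR fit -> internal (CV) and external validation ->
Y-randomization -> applicability-domain analysis.  Each stage's report is
written as JSON/CSV next to a resolved copy of the configuration; any stage
failure aborts with an error naming the stage.

A validation-only mode consumes experimental/predicted tables directly (no
descriptor matrix needed), so published model statistics can be recomputed
even when the descriptor matrices behind them are unavailable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (QSRRDataset, PredictionTable, filter_descriptors,
                      load_dataset)
from .domain import ADReport, williams_data
from .firefly import FireflyConfig, SelectionResult, select_descriptors
from .linearity import LinearityReport, linearity_screen
from .svr import SVRConfig, SVRModel, fit_svr, predict
from .validation import (CVScheme, MetricsReport, cross_validate,
                         evaluate_pairs)
from .yrandom import YRandReport, run_y_randomization

__all__ = ["PipelineConfig", "RunBundle", "run_pipeline", "report_table"]

log = logging.getLogger("qsrr")

METRIC_ROWS = [
    ("r2_cal", "R2_cal"),
    ("r2_adj", "R2_cal-adj"),
    ("q2_cv", "q2_CV"),
    ("r2_pred", "R2_pred"),
    ("rmse_cal", "RMSE_cal"),
    ("rmse_cv", "RMSE_CV"),
    ("rmse_pred", "RMSE_pred"),
    ("rho_cal", "rho_cal"),
    ("rho_cv", "rho_CV"),
    ("rho_pred", "rho_pred"),
]


@dataclass
class PipelineConfig:
    data_path: str
    response_column: str = "k"
    id_columns: tuple[str, ...] = ("observation_id",)
    test_ids: tuple[str, ...] = ()
    firefly: FireflyConfig = field(default_factory=FireflyConfig)
    svr: SVRConfig = field(default_factory=SVRConfig)
    cv: CVScheme = field(default_factory=CVScheme)
    yrand_iterations: int = 20
    yrand_mode: str = "auto"
    ad_alpha: float = 0.05
    out_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunBundle:
    config: PipelineConfig
    removal_log: list[tuple[str, str]]
    linearity: LinearityReport
    selection: SelectionResult
    model: SVRModel
    predictions: PredictionTable
    metrics: MetricsReport
    yrand: YRandReport
    ad: ADReport
    seed: int


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig,
                 dataset: QSRRDataset | None = None) -> RunBundle:
    """Execute the full workflow; see module docstring for the stage order.

    ``dataset`` may be passed directly (it then overrides ``data_path``).
    Component seeds are derived from the master seed by fixed offsets so a
    rerun with the same config and seed is bit-identical.
    """
    seed = config.seed
    if dataset is None:
        dataset = _stage("load")(load_dataset)(
            config.data_path, config.response_column, config.id_columns
        )
    log.info("loaded dataset: n=%d, p=%d", dataset.n, dataset.p)

    dataset, removal_log = _stage("filter")(filter_descriptors)(dataset)
    log.info("variance filter removed %d descriptors, p=%d",
             len(removal_log), dataset.p)

    if config.test_ids:
        from .dataset import assign_split
        dataset = _stage("split")(assign_split)(dataset, list(config.test_ids))
    if not dataset.train_mask.any():
        raise StageError("stage 'split' failed: no training rows assigned")

    lin = _stage("linearity")(linearity_screen)(dataset)
    log.info("linearity screen: DW=%.3f p=%.3g verdict=%s",
             lin.dw_statistic, lin.p_value, lin.verdict)

    ffa = dataclasses.replace(config.firefly, seed=seed)
    n_train = int(dataset.train_mask.sum())
    if ffa.max_descriptors is None and dataset.p >= n_train - 2:
        # parsimony cap so the selected design stays estimable (leverage/AD
        # need n_train > p_selected + 1); retention models are small anyway
        ffa = dataclasses.replace(ffa, max_descriptors=max(1, n_train // 3))
        log.info("descriptor count rivals n_train; capping subsets at %d",
                 ffa.max_descriptors)
    cv = dataclasses.replace(config.cv, seed=seed + 1)
    sel = _stage("selection")(select_descriptors)(
        dataset, ffa, config.svr, cv,
        progress=lambda g, f, k: log.info(
            "generation %d: best RMSE_CV=%.4f, %d descriptors", g, f, k),
    )
    log.info("selected %d descriptors: %s (RMSE_CV=%.4f)",
             len(sel.selected_descriptor_names),
             ", ".join(sel.selected_descriptor_names), sel.final_fitness)

    tr, te = dataset.train_mask, dataset.test_mask
    cols = np.flatnonzero(sel.selected_mask)
    model = _stage("fit")(fit_svr)(
        dataset.X[np.ix_(tr, cols)], dataset.y[tr], config.svr,
        descriptor_names=sel.selected_descriptor_names,
    )
    y_cal = predict(model, dataset.X[np.ix_(tr, cols)])
    y_cv = _stage("cv")(cross_validate)(dataset, sel.selected_mask,
                                        config.svr, cv)
    y_te = predict(model, dataset.X[np.ix_(te, cols)]) if te.any() else None

    n = dataset.n
    pred_train = np.full(n, np.nan)
    pred_cv = np.full(n, np.nan)
    pred_test = np.full(n, np.nan)
    pred_train[tr] = y_cal
    pred_cv[tr] = y_cv
    if y_te is not None:
        pred_test[te] = y_te
    table = PredictionTable(list(dataset.observation_ids), dataset.split,
                            dataset.y, pred_train, pred_cv, pred_test)
    metrics = _stage("metrics")(evaluate_pairs)(table, p=len(cols))

    yrand = _stage("y_randomization")(run_y_randomization)(
        dataset, ffa, config.svr, cv,
        n_iterations=config.yrand_iterations, seed=seed + 2,
        mode=config.yrand_mode, original_mask=sel.selected_mask,
    )
    ad = _stage("applicability_domain")(williams_data)(
        dataset.X[np.ix_(tr, cols)], y_cv - dataset.y[tr],
        [dataset.observation_ids[i] for i in np.flatnonzero(tr)],
        dataset.X[np.ix_(te, cols)] if te.any() else None,
        (y_te - dataset.y[te]) if y_te is not None else None,
        [dataset.observation_ids[i] for i in np.flatnonzero(te)] or None,
        alpha=config.ad_alpha,
    )
    bundle = RunBundle(config, removal_log, lin, sel, model, table, metrics,
                       yrand, ad, seed)
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: RunBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(bundle.config.to_dict(), indent=1, default=str))
    (out / "linearity.json").write_text(
        json.dumps(bundle.linearity.to_dict(), indent=1))
    (out / "selection.json").write_text(json.dumps({
        "selected_descriptor_names": bundle.selection.selected_descriptor_names,
        "final_fitness": bundle.selection.final_fitness,
        "history": bundle.selection.history,
        "seed": bundle.selection.seed,
        "n_fitness_evaluations": bundle.selection.n_fitness_evaluations,
        "n_cache_hits": bundle.selection.n_cache_hits,
    }, indent=1))
    bundle.model.to_json(out / "model.json")
    (out / "metrics.json").write_text(
        json.dumps(bundle.metrics.rounded(), indent=1))
    (out / "yrand.json").write_text(json.dumps({
        k: v for k, v in dataclasses.asdict(bundle.yrand).items()
    }, indent=1, default=float))
    bundle.ad.to_frame().to_csv(out / "williams.csv", index=False)
    pd.DataFrame({
        "observation_id": bundle.predictions.observation_ids,
        "split": bundle.predictions.split,
        "k_exp": bundle.predictions.y_experimental,
        "k_pred_cal": bundle.predictions.y_predicted_train,
        "k_pred_cv": bundle.predictions.y_predicted_cv,
        "k_pred_test": bundle.predictions.y_predicted_test,
    }).to_csv(out / "predictions.csv", index=False)


def report_table(reports: dict[str, MetricsReport], ndigits: int = 3) -> pd.DataFrame:
    """Metric-by-model performance table (the published-table layout).

    Rows are metrics, columns are model names; entries are rounded to
    ``ndigits`` decimals at presentation time only.
    """
    if not reports:
        raise ValueError("no metrics reports given")
    data = {}
    for name, rep in reports.items():
        col = {}
        for key, label in METRIC_ROWS:
            v = getattr(rep, key)
            col[label] = f"{v:.{ndigits}f}" if v is not None else "---"
        data[name] = col
    return pd.DataFrame(data)
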