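"""Y-randomization (response-scrambling) validation.

The training responses are randomly permuted while the descriptor matrix is
left untouched; the full selection-and-fit protocol is rerun on each scrambled
copy.  If the original model's quality is genuinely driven by a
structure-retention link, scrambled models must degrade sharply.  The summary
statistic is

    cRp^2 = sqrt(R^2) * sqrt(R^2 - Ry^2),

with R^2 the original model's squared correlation and Ry^2 the mean squared
correlation of the scrambled models; values above 0.5 are taken as evidence
against chance correlation.  When R^2 < Ry^2 the margin is negative and the
statistic is undefined: NaN is returned and flagged (model no better than
chance), not raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Literal

import numpy as np

from .dataset import QSRRDataset
from .firefly import FireflyConfig, select_descriptors
from .svr import SVRConfig, fit_svr, predict
from .validation import CVScheme, cross_validate, r_squared

__all__ = ["YRandReport", "scramble_response", "c_rp2", "run_y_randomization"]

CRP2_THRESHOLD = 0.5


def scramble_response(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the response vector."""
    y = np.asarray(y)
    if len(y) < 2:
        raise ValueError("need at least 2 responses to scramble")
    return y[rng.permutation(len(y))]


def c_rp2(R2_original: float, R2_y_mean: float) -> float:
    """cRp^2 = sqrt(R^2) * sqrt(R^2 - Ry^2); NaN when the margin is negative."""
    for name, v in [("R2_original", R2_original), ("R2_y_mean", R2_y_mean)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if R2_original < R2_y_mean:
        return float("nan")
    return sqrt(R2_original) * sqrt(R2_original - R2_y_mean)


@dataclass
class YRandReport:
    n_iterations: int
    mode: Literal["full", "fixed_mask"]
    r2_original_cal: float
    q2_original_cv: float
    r2_scrambled: list[float] = field(default_factory=list)   # per iteration
    q2_scrambled: list[float] = field(default_factory=list)
    mean_r2_scrambled: float = float("nan")
    mean_q2_scrambled: float = float("nan")
    c_rp2_cal: float = float("nan")
    c_rp2_cv: float = float("nan")
    chance_flag: bool = False     # original model no better than scrambled
    seed: int = 0

    @property
    def passed(self) -> bool:
        return (not self.chance_flag) and self.c_rp2_cv > CRP2_THRESHOLD


def _model_stats(ds: QSRRDataset, mask: np.ndarray, svr_config: SVRConfig,
                 scheme: CVScheme) -> tuple[float, float]:
    """(calibration R^2, cross-validated q^2) of an SVR on the masked columns."""
    tr = ds.train_mask
    cols = np.flatnonzero(mask)
    model = fit_svr(ds.X[np.ix_(tr, cols)], ds.y[tr], svr_config)
    y_cal = predict(model, ds.X[np.ix_(tr, cols)])
    y_cv = cross_validate(ds, mask, svr_config, scheme)
    try:
        r2_cal = r_squared(ds.y[tr], y_cal)
    except ValueError:  # constant predictions: no explanatory power
        r2_cal = 0.0
    try:
        q2 = r_squared(ds.y[tr], y_cv)
    except ValueError:
        q2 = 0.0
    return r2_cal, q2


def run_y_randomization(
    dataset: QSRRDataset,
    ffa_config: FireflyConfig,
    svr_config: SVRConfig = SVRConfig(),
    cv_scheme: CVScheme = CVScheme("leave_one_out"),
    n_iterations: int = 100,
    seed: int = 0,
    mode: Literal["auto", "full", "fixed_mask"] = "auto",
    original_mask: np.ndarray | None = None,
) -> YRandReport:
    """Scramble-and-refit validation of a selection+SVR protocol.

    ``full`` reruns descriptor selection on every scrambled copy (the
    reference protocol); ``fixed_mask`` reuses ``original_mask`` and only
    refits the SVR -- ~selection-cost cheaper, clearly labeled in the report.
    ``auto`` picks ``full`` for n_iterations <= 20, else ``fixed_mask``.
    Per-iteration seeds are derived from ``seed`` by counter, so the report is
    fully deterministic.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if mode == "auto":
        mode = "full" if n_iterations <= 20 else "fixed_mask"

    if original_mask is None:
        sel = select_descriptors(
            dataset,
            FireflyConfig(**{**ffa_config.__dict__, "seed": seed}),
            svr_config, cv_scheme,
        )
        original_mask = sel.selected_mask
    original_mask = np.asarray(original_mask, bool)
    r2_orig, q2_orig = _model_stats(dataset, original_mask, svr_config, cv_scheme)

    tr = dataset.train_mask
    r2_s: list[float] = []
    q2_s: list[float] = []
    for it in range(n_iterations):
        rng = np.random.default_rng(seed + 1000 + it)
        ds_scrambled = QSRRDataset(
            list(dataset.observation_ids),
            list(dataset.descriptor_names),
            dataset.X,
            _scramble_train(dataset.y, tr, rng),
            dataset.split,
        )
        if mode == "full":
            sel_i = select_descriptors(
                ds_scrambled,
                FireflyConfig(**{**ffa_config.__dict__, "seed": seed + 2000 + it}),
                svr_config, cv_scheme,
            )
            mask_i = sel_i.selected_mask
        else:
            mask_i = original_mask
        r2_i, q2_i = _model_stats(ds_scrambled, mask_i, svr_config, cv_scheme)
        r2_s.append(r2_i)
        q2_s.append(q2_i)

    mean_r2 = float(np.mean(r2_s))
    mean_q2 = float(np.mean(np.clip(q2_s, 0.0, 1.0)))
    crp2_cal = c_rp2(r2_orig, min(mean_r2, 1.0))
    crp2_cv = c_rp2(q2_orig, mean_q2) if 0 <= q2_orig <= 1 else float("nan")
    return YRandReport(
        n_iterations=n_iterations,
        mode=mode,
        r2_original_cal=r2_orig,
        q2_original_cv=q2_orig,
        r2_scrambled=r2_s,
        q2_scrambled=q2_s,
        mean_r2_scrambled=mean_r2,
        mean_q2_scrambled=mean_q2,
        c_rp2_cal=crp2_cal,
        c_rp2_cv=crp2_cv,
        chance_flag=bool(np.isnan(crp2_cal) or np.isnan(crp2_cv)),
        seed=seed,
    )


def _scramble_train(y: np.ndarray, train_mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Permute the response on the training rows only; test rows untouched."""
    out = np.array(y, dtype=float)
    idx = np.flatnonzero(train_mask)
    out[idx] = scramble_response(y[idx], rng)
    return out
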