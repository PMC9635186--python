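"""Cross-validation engines and the model-performance metric suite.

Metric conventions (verified against the packaged prediction tables):

* R^2 (calibration, prediction) and q^2 (cross-validation) are the *squared
  Pearson correlation* between observed and predicted values.  The
  coefficient-of-determination form 1 - PRESS/SS_tot gives a materially
  different q^2 (~0.715 vs 0.808 on the packaged quinolone CV column) and is
  therefore not what the packaged tables report.
* RMSE = sqrt(mean squared (predicted - observed)).
* rho is Spearman's rank correlation (average ranks on ties) -- fidelity of
  the predicted elution order.
* adjusted R^2 uses the standard 1 - (1-R^2)(n-1)/(n-p-1).  Note the source
  tables print adjusted values (0.926, 0.896) that this standard formula does
  not reproduce (0.897, 0.888); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import ceil
from typing import Literal

import numpy as np
from scipy import stats

from .dataset import QSRRDataset, PredictionTable
from .svr import SVRConfig, fit_svr, predict

__all__ = [
    "CVScheme",
    "MetricsReport",
    "r_squared",
    "adjusted_r_squared",
    "rmse",
    "spearman_rho",
    "cross_validate",
    "cv_rmse",
    "evaluate_model",
    "evaluate_pairs",
]


# ---------------------------------------------------------------------------
# metrics


def r_squared(y_obs: np.ndarray, y_hat: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y_obs = np.asarray(y_obs, float)
    y_hat = np.asarray(y_hat, float)
    if len(y_obs) != len(y_hat):
        raise ValueError("length mismatch")
    if len(y_obs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(y_obs) == 0 or np.ptp(y_hat) == 0:
        raise ValueError("correlation undefined for a constant input")
    r = np.corrcoef(y_obs, y_hat)[0, 1]
    return float(r * r)


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n-1)/(n-p-1); requires n > p + 1."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def rmse(y_obs: np.ndarray, y_hat: np.ndarray) -> float:
    y_obs = np.asarray(y_obs, float)
    y_hat = np.asarray(y_hat, float)
    if len(y_obs) != len(y_hat) or len(y_obs) == 0:
        raise ValueError("need equal nonzero lengths")
    return float(np.sqrt(np.mean((y_hat - y_obs) ** 2)))


def spearman_rho(y_obs: np.ndarray, y_hat: np.ndarray) -> float:
    """Spearman rank correlation with average ranks on ties."""
    y_obs = np.asarray(y_obs, float)
    y_hat = np.asarray(y_hat, float)
    if len(y_obs) != len(y_hat) or len(y_obs) < 3:
        raise ValueError("need at least 3 pairs of equal length")
    return float(stats.spearmanr(y_obs, y_hat).statistic)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVScheme:
    """Internal-validation scheme.

    ``leave_one_out`` has exactly n_train folds.  ``leave_k_percent_out``
    makes one seeded random partition of the training rows into disjoint folds
    of size ceil(percent/100 * n) (the last fold may be smaller), covering
    every observation exactly once per repeat.
    """

    kind: Literal["leave_one_out", "leave_k_percent_out"] = "leave_one_out"
    percent: float = 10.0
    n_repeats: int = 1
    seed: int = 0

    def folds(self, n: int) -> list[np.ndarray]:
        if self.kind == "leave_one_out":
            return [np.array([i]) for i in range(n)]
        size = max(1, ceil(self.percent / 100.0 * n))
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        return [perm[i:i + size] for i in range(0, n, size)]


def cross_validate(
    dataset: QSRRDataset,
    mask: np.ndarray | list[str] | None,
    svr_config: SVRConfig,
    scheme: CVScheme,
) -> np.ndarray:
    """Out-of-fold predictions for every training observation.

    ``mask`` selects descriptor columns (boolean array over columns, a list of
    descriptor names, or None for all).  Each fold is fitted on the remaining
    training rows only -- standardization statistics are recomputed inside the
    fold, so no information leaks from the held-out rows.  With
    ``n_repeats > 1`` the per-observation predictions are averaged over
    repeated random partitions.
    """
    train_rows = np.flatnonzero(dataset.train_mask)
    if len(train_rows) == 0:
        raise ValueError("dataset has no training rows")
    if mask is None:
        cols = np.arange(dataset.p)
    elif isinstance(mask, (list, tuple)) and mask and isinstance(mask[0], str):
        cols = np.array([dataset.descriptor_names.index(m) for m in mask])
    else:
        mask = np.asarray(mask)
        cols = np.flatnonzero(mask) if mask.dtype == bool else mask
    X = dataset.X[np.ix_(train_rows, cols)]
    y = dataset.y[train_rows]
    n = len(train_rows)

    out = np.zeros(n)
    for rep in range(scheme.n_repeats):
        rep_scheme = CVScheme(scheme.kind, scheme.percent, 1, scheme.seed + rep)
        pred = np.full(n, np.nan)
        for fold in rep_scheme.folds(n):
            keep = np.setdiff1d(np.arange(n), fold)
            if len(keep) < 2:
                raise ValueError("CV fold leaves fewer than 2 training rows")
            model = fit_svr(X[keep], y[keep], svr_config)
            pred[fold] = predict(model, X[fold])
        out += pred
    return out / scheme.n_repeats


def cv_rmse(dataset: QSRRDataset, mask, svr_config: SVRConfig,
            scheme: CVScheme) -> float:
    """RMSE of the out-of-fold predictions (the selection fitness)."""
    y_cv = cross_validate(dataset, mask, svr_config, scheme)
    return rmse(dataset.y[dataset.train_mask], y_cv)


# ---------------------------------------------------------------------------
# reporting


@dataclass
class MetricsReport:
    """The performance-table twin: calibration / CV / external-test metrics."""

    n_train: int
    n_test: int
    p_descriptors: int
    r2_cal: float | None = None
    r2_adj: float | None = None
    q2_cv: float | None = None
    r2_pred: float | None = None
    rmse_cal: float | None = None
    rmse_cv: float | None = None
    rmse_pred: float | None = None
    rho_cal: float | None = None
    rho_cv: float | None = None
    rho_pred: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        """Serialization view; internal values stay full precision."""
        return {
            k: (round(v, ndigits) if isinstance(v, float) else v)
            for k, v in asdict(self).items()
        }


def evaluate_pairs(
    table: PredictionTable, n_train: int | None = None, p: int | None = None
) -> MetricsReport:
    """Compute every applicable metric from a prediction table.

    A metric is present iff its prediction column is populated.  ``p`` (the
    number of selected descriptors) is only needed for adjusted R^2.
    """
    n_train = int(table.train_mask.sum()) if n_train is None else n_train
    n_test = int(table.test_mask.sum())
    report = MetricsReport(n_train=n_train, n_test=n_test, p_descriptors=p or 0)
    for which, r2_name, rmse_name, rho_name in [
        ("train", "r2_cal", "rmse_cal", "rho_cal"),
        ("cv", "q2_cv", "rmse_cv", "rho_cv"),
        ("test", "r2_pred", "rmse_pred", "rho_pred"),
    ]:
        obs, pred = table.pairs(which)
        if len(obs) == 0:
            continue
        setattr(report, r2_name, r_squared(obs, pred))
        setattr(report, rmse_name, rmse(obs, pred))
        setattr(report, rho_name, spearman_rho(obs, pred))
    if report.r2_cal is not None and p and n_train > p + 1:
        report.r2_adj = adjusted_r_squared(report.r2_cal, n_train, p)
    return report


# spec name for the same operation
evaluate_model = evaluate_pairs
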