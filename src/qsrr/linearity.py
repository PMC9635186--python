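"""Linearity screening: augmented partial residual plots + Durbin-Watson.

The modeling choice between a linear model and a kernel learner is gated by a
nonlinearity screen.  For a candidate descriptor x_j the augmented partial
residual plot (APARP) shows e_i + b_j x_ij + c x_ij^2 against x_ij, where e,
b_j and c come from the least-squares fit y = b0 + X b + c x_j^2; curvature
left unexplained by a linear model bends this series.  The formal test orders
the *linear* model's residuals by x_j and applies the Durbin-Watson statistic

    DW = sum_{i>=2} (e_(i) - e_(i-1))^2 / sum e_(i)^2  in [0, 4],

whose lower tail (positive serial correlation along the descriptor axis)
signals systematic curvature.  P-values use the normal approximation with the
design-dependent null moments of DW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import QSRRDataset

__all__ = ["LinearityReport", "aparp", "durbin_watson", "linearity_screen"]

ALPHA = 0.05


def aparp(y: np.ndarray, X: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Augmented partial residual series for descriptor ``j``.

    Fits y = b0 + X b + c x_j^2 by least squares and returns
    ``(x_j_sorted, augmented_partial_residual_sorted)`` where the augmented
    partial residual of observation i is e_i + b_j x_ij + c x_ij^2.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n > p+2 (got n={n}, p={p})")
    xj = X[:, j]
    design = np.column_stack([np.ones(n), X, xj ** 2])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("singular APARP design matrix")
    resid = y - design @ coef
    apr = resid + coef[1 + j] * xj + coef[-1] * xj ** 2
    order = np.argsort(xj, kind="stable")
    return xj[order], apr[order]


def _dw_statistic(e: np.ndarray) -> float:
    return float(np.sum(np.diff(e) ** 2) / np.sum(e ** 2))


def durbin_watson(ordered_residuals: np.ndarray,
                  design: np.ndarray | None = None) -> tuple[float, float]:
    """Durbin-Watson statistic and one-sided p-value for positive correlation.

    ``ordered_residuals`` must already be in the ordering under test (here:
    ascending descriptor value).  When ``design`` (the regressor matrix
    including intercept, same ordering) is given, the null mean/variance use
    the design-dependent moments E[d] = tr(MA)/(n-k) and
    Var[d] = 2[tr((MA)^2) - (n-k) E[d]^2] / ((n-k)(n-k+2)); otherwise the
    identity-projection (raw iid series) moments are used.  The p-value is the
    lower-tail normal probability P(DW < d).
    """
    e = np.asarray(ordered_residuals, float)
    n = len(e)
    if n < 6:
        raise ValueError("need at least 6 residuals")
    if np.all(e == 0):
        raise ValueError("all-zero residuals")
    d = _dw_statistic(e)

    # difference-operator matrix A: d = e'Ae / e'e
    A = np.zeros((n, n))
    i = np.arange(n)
    A[i, i] = 2.0
    A[0, 0] = A[-1, -1] = 1.0
    A[i[:-1], i[:-1] + 1] = -1.0
    A[i[:-1] + 1, i[:-1]] = -1.0

    if design is None:
        M = np.eye(n)
        k = 0
    else:
        Xd = np.atleast_2d(np.asarray(design, float))
        k = np.linalg.matrix_rank(Xd)
        # projection onto the orthogonal complement of the column space
        Q, _ = np.linalg.qr(Xd)
        M = np.eye(n) - Q @ Q.T
    nu = n - k
    MA = M @ A
    mean_d = np.trace(MA) / nu
    var_d = 2.0 * (np.trace(MA @ MA) - nu * mean_d ** 2) / (nu * (nu + 2))
    var_d = max(var_d, 1e-12)
    p_value = float(stats.norm.cdf((d - mean_d) / np.sqrt(var_d)))
    return d, p_value


@dataclass
class LinearityReport:
    dw_statistic: float            # of the most nonlinear descriptor
    p_value: float                 # Bonferroni-adjusted minimum
    verdict: str                   # "linear" | "nonlinear" at alpha = 0.05
    alpha: float = ALPHA
    per_descriptor: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dw_statistic": self.dw_statistic,
            "p_value": self.p_value,
            "verdict": self.verdict,
            "alpha": self.alpha,
            "per_descriptor": self.per_descriptor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearityReport":
        return cls(d["dw_statistic"], d["p_value"], d["verdict"], d["alpha"],
                   d["per_descriptor"])


def linearity_screen(dataset: QSRRDataset,
                     descriptors: list[str] | None = None,
                     alpha: float = ALPHA) -> LinearityReport:
    """Durbin-Watson nonlinearity screen over (a subset of) descriptors.

    For each screened descriptor the residuals of a least-squares *linear*
    fit are ordered by that descriptor and tested with DW; unmodeled
    curvature appears as positive serial correlation.  When the full
    multivariate fit is feasible (n > p+2) its residuals are used; otherwise
    each descriptor is screened with its own univariate fit (high-dimensional
    fallback).  The verdict aggregates by the minimum Bonferroni-adjusted
    p-value: nonlinear iff it is below ``alpha``.  Raw per-descriptor DW
    statistics, p-values and APARP series are kept in the report.
    """
    rows = dataset.train_mask if dataset.train_mask.any() else np.ones(
        dataset.n, dtype=bool)
    X = dataset.X[rows]
    y = dataset.y[rows]
    names = descriptors if descriptors is not None else dataset.descriptor_names
    if not names:
        raise ValueError("no descriptors to screen")
    n = len(y)
    multivariate = n > dataset.p + 2 and descriptors is None

    per: dict[str, dict] = {}
    if multivariate:
        design = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid_full = y - design @ coef

    for name in names:
        j = dataset.descriptor_names.index(name)
        xj = X[:, j]
        if np.ptp(xj) == 0:
            continue  # constant within the screened rows: no ordering
        order = np.argsort(xj, kind="stable")
        if multivariate:
            resid = resid_full
            dsg = design
        else:
            dsg = np.column_stack([np.ones(n), xj])
            coef, *_ = np.linalg.lstsq(dsg, y, rcond=None)
            resid = y - dsg @ coef
        dw, p = durbin_watson(resid[order], dsg[order])
        xs, apr = aparp(y, xj[:, None], 0) if not multivariate else aparp(
            y, X, j)
        per[name] = {
            "dw": dw,
            "p_raw": p,
            "aparp_x": xs.tolist(),
            "aparp_residual": apr.tolist(),
        }
    if not per:
        raise ValueError("no screenable (non-constant) descriptors")
    m = len(per)
    worst = min(per, key=lambda k: per[k]["p_raw"])
    p_adj = min(1.0, per[worst]["p_raw"] * m)
    for v in per.values():
        v["p_bonferroni"] = min(1.0, v["p_raw"] * m)
    verdict = "nonlinear" if p_adj < alpha else "linear"
    return LinearityReport(per[worst]["dw"], p_adj, verdict, alpha, per)
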