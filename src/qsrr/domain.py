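"""Applicability-domain analysis: leverage/Williams plot and Hotelling T^2.

The applicability domain (AD) is the descriptor-space region spanned by the
training set, inside which model predictions are considered reliable.  Two
standard views are provided:

* Williams plot -- leverage h (hat-matrix quadratic form on the
  intercept-augmented, training-standardized selected descriptors) against
  standardized residuals; a point is in-domain iff h <= h* = 3(p+1)/n_train
  and |residual / SD(residuals)| <= 3.
* Hotelling T^2 -- Mahalanobis-type distance from the training centroid with
  an F-distribution critical value at level alpha.

Leverages of new points use the training-only hat matrix (standard practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ADReport",
    "leverage",
    "leverage_threshold",
    "standardized_residuals",
    "williams_data",
    "hotelling_t2",
]


def _augment(X: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    Z = (X - mean) / scale
    return np.hstack([np.ones((len(Z), 1)), Z])


def leverage(X_train_selected: np.ndarray,
             X_query_selected: np.ndarray | None = None) -> np.ndarray:
    """Leverages h(x) = x~' (X~'X~)^-1 x~ on intercept-augmented coordinates.

    Columns are standardized with training statistics before augmentation
    (leverage itself is invariant to affine column rescaling; standardizing
    keeps the cross-product well conditioned).  With no query, returns the
    training hat-matrix diagonal, which sums to p+1.
    """
    X_train_selected = np.atleast_2d(np.asarray(X_train_selected, float))
    n, p = X_train_selected.shape
    if n <= p + 1:
        raise ValueError(f"need n_train > p+1 (got n={n}, p={p})")
    mean = X_train_selected.mean(axis=0)
    scale = X_train_selected.std(axis=0, ddof=0)
    scale = np.where(scale <= 1e-12, 1.0, scale)
    A = _augment(X_train_selected, mean, scale)
    gram = A.T @ A
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular cross-product: selected descriptors are collinear"
        ) from None
    # guard against a numerically singular but invertible cross-product
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError(
            "near-singular cross-product: selected descriptors are collinear"
        )
    Q = A if X_query_selected is None else _augment(
        np.atleast_2d(np.asarray(X_query_selected, float)), mean, scale
    )
    return np.einsum("ij,jk,ik->i", Q, gram_inv, Q)


def leverage_threshold(n_train: int, p: int) -> float:
    """Warning leverage h* = 3(p+1)/n_train."""
    if n_train <= p + 1:
        raise ValueError(f"need n_train > p+1 (got n={n_train}, p={p})")
    return 3.0 * (p + 1) / n_train


def standardized_residuals(residuals: np.ndarray) -> np.ndarray:
    """residual / sample SD of the residuals (n-1 denominator)."""
    residuals = np.asarray(residuals, float)
    if len(residuals) < 3:
        raise ValueError("need at least 3 residuals")
    sd = residuals.std(ddof=1)
    if sd <= 0:
        raise ValueError("residual SD is zero; standardization undefined")
    return residuals / sd


@dataclass
class ADReport:
    """Plot-ready Williams data plus Hotelling flags per observation."""

    observation_ids: list[str]
    set_label: np.ndarray          # "train" (CV residuals) / "test"
    leverages: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    in_domain: np.ndarray
    hotelling_t2: np.ndarray | None = None
    hotelling_critical: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "observation_id": self.observation_ids,
            "set": self.set_label,
            "leverage": self.leverages,
            "std_residual": self.std_residuals,
            "in_domain": self.in_domain,
        })
        if self.hotelling_t2 is not None:
            df["hotelling_t2"] = self.hotelling_t2
            df["hotelling_flag"] = self.hotelling_t2 > self.hotelling_critical
        return df


def williams_data(
    X_train_selected: np.ndarray,
    residuals_train: np.ndarray,
    observation_ids_train: list[str],
    X_test_selected: np.ndarray | None = None,
    residuals_test: np.ndarray | None = None,
    observation_ids_test: list[str] | None = None,
    alpha: float = 0.05,
) -> ADReport:
    """Williams-plot table for a fitted model.

    Training rows are plotted with their cross-validation residuals, test rows
    with their external-prediction residuals (the convention of the packaged
    models).  Residuals of both sets are standardized jointly by the pooled
    residual SD.  in_domain <=> h <= h* and |standardized residual| <= 3.
    """
    h_train = leverage(X_train_selected)
    n, p = np.atleast_2d(X_train_selected).shape
    h_star = leverage_threshold(n, p)
    ids = list(observation_ids_train)
    labels = ["train"] * n
    h_all = [h_train]
    res_all = [np.asarray(residuals_train, float)]
    if X_test_selected is not None and len(X_test_selected):
        h_all.append(leverage(X_train_selected, X_test_selected))
        res_all.append(np.asarray(residuals_test, float))
        ids += list(observation_ids_test)
        labels += ["test"] * len(X_test_selected)
    h = np.concatenate(h_all)
    res = np.concatenate(res_all)
    z = standardized_residuals(res)
    in_domain = (h <= h_star) & (np.abs(z) <= 3.0)
    t2, t2_crit = hotelling_t2(
        X_train_selected,
        np.vstack([np.atleast_2d(X_train_selected)] + (
            [np.atleast_2d(X_test_selected)] if X_test_selected is not None
            and len(X_test_selected) else [])),
        alpha=alpha,
    )
    return ADReport(
        observation_ids=ids,
        set_label=np.array(labels, dtype=object),
        leverages=h,
        std_residuals=z,
        h_star=h_star,
        in_domain=in_domain,
        hotelling_t2=t2,
        hotelling_critical=t2_crit,
    )


def hotelling_t2(
    X_train_selected: np.ndarray,
    X_query_selected: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Hotelling T^2(x) = (x - xbar)' S^-1 (x - xbar) plus its critical value.

    S is the training sample covariance (n-1 denominator); the critical value
    is p(n-1)/(n-p) * F(1-alpha; p, n-p).
    """
    X = np.atleast_2d(np.asarray(X_train_selected, float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n_train > p (got n={n}, p={p})")
    mean = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    if np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError("singular training covariance")
    S_inv = np.linalg.inv(S)
    Q = X if X_query_selected is None else np.atleast_2d(
        np.asarray(X_query_selected, float)
    )
    D = Q - mean
    t2 = np.einsum("ij,jk,ik->i", D, S_inv, D)
    critical = p * (n - 1) / (n - p) * stats.f.ppf(1.0 - alpha, p, n - p)
    return t2, float(critical)
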