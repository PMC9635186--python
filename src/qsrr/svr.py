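"""Epsilon-insensitive support vector regression (the modeling core).

The regression function is f(x) = sum_i a_i K(s_i, x) + b over support
vectors s_i, obtained from the standard epsilon-SVR dual.  The dual problem is
solved by scikit-learn's libsvm binding; the fitted model is stored as plain
arrays (support vectors, dual coefficients, bias, standardization statistics)
so prediction is an explicit kernel expansion and models serialize to JSON.

Defaults follow the retention-modeling setup the package ships fixtures for:
RBF kernel, C = 1, epsilon = 0.01, kernel width gamma = 1/p_selected ("auto"),
with train-fold z-scoring of descriptors (RBF distances are meaningless across
raw descriptor scales).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from sklearn.svm import SVR as _SkSVR

__all__ = ["SVRConfig", "SVRModel", "rbf_kernel", "fit_svr", "predict"]


@dataclass(frozen=True)
class SVRConfig:
    """Hyper-parameters of the epsilon-SVR model."""

    C: float = 1.0
    epsilon: float = 0.01
    kernel: Literal["rbf", "polynomial", "sigmoid"] = "rbf"
    gamma_kernel: float | Literal["auto"] = "auto"  # "auto" -> 1/p_selected
    degree: int = 3          # polynomial kernel only
    coef0: float = 0.0       # polynomial / sigmoid kernels
    standardize: bool = True
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.kernel not in ("rbf", "polynomial", "sigmoid"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.gamma_kernel != "auto" and self.gamma_kernel <= 0:
            raise ValueError("gamma_kernel must be > 0 or 'auto'")

    def resolve_gamma(self, p: int) -> float:
        return 1.0 / p if self.gamma_kernel == "auto" else float(self.gamma_kernel)


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma_kernel: float) -> float:
    """Gaussian similarity exp(-gamma * ||u - v||^2), in (0, 1]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("rbf_kernel requires equal-length vectors")
    return float(np.exp(-gamma_kernel * np.sum((u - v) ** 2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, config: SVRConfig,
                   gamma: float) -> np.ndarray:
    if config.kernel == "rbf":
        d2 = (
            (A ** 2).sum(1)[:, None] + (B ** 2).sum(1)[None, :] - 2.0 * A @ B.T
        )
        return np.exp(-gamma * np.maximum(d2, 0.0))
    lin = gamma * A @ B.T + config.coef0
    if config.kernel == "polynomial":
        return lin ** config.degree
    return np.tanh(lin)  # sigmoid


@dataclass
class SVRModel:
    """A fitted epsilon-SVR model as an explicit kernel expansion."""

    config: SVRConfig
    support_vectors: np.ndarray   # (n_sv, p), standardized coordinates
    dual_coef: np.ndarray         # (n_sv,), alpha_i - alpha_i^*
    bias: float
    gamma: float                  # resolved kernel width
    x_mean: np.ndarray            # standardization statistics (identity if off)
    x_scale: np.ndarray
    descriptor_names: list[str] | None = None
    passthrough_columns: list[int] = field(default_factory=list)

    @property
    def n_support(self) -> int:
        return len(self.dual_coef)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) / self.x_scale

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": asdict(self.config),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "descriptor_names": self.descriptor_names,
            "passthrough_columns": self.passthrough_columns,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SVRModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            config=SVRConfig(**d["config"]),
            support_vectors=np.asarray(d["support_vectors"], float),
            dual_coef=np.asarray(d["dual_coef"], float),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            x_mean=np.asarray(d["x_mean"], float),
            x_scale=np.asarray(d["x_scale"], float),
            descriptor_names=d.get("descriptor_names"),
            passthrough_columns=list(d.get("passthrough_columns", [])),
        )


def fit_svr(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: SVRConfig = SVRConfig(),
    descriptor_names: list[str] | None = None,
) -> SVRModel:
    """Fit epsilon-SVR on the (selected-descriptor) training block.

    Standardization (when on) z-scores each column with training statistics;
    a zero-variance column is passed through unscaled (recorded in
    ``passthrough_columns``) rather than raising, since constant columns can
    appear inside CV folds even after dataset-level filtering.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("need a 2-D X_train with at least 2 rows")
    if X_train.shape[1] < 1:
        raise ValueError("need at least one descriptor column")
    n, p = X_train.shape

    passthrough: list[int] = []
    if config.standardize:
        mean = X_train.mean(axis=0)
        scale = X_train.std(axis=0, ddof=0)
        zero = scale <= 1e-12 * np.maximum(1.0, np.abs(mean))
        if np.any(zero):
            passthrough = [int(j) for j in np.flatnonzero(zero)]
            mean = np.where(zero, 0.0, mean)
            scale = np.where(zero, 1.0, scale)
    else:
        mean = np.zeros(p)
        scale = np.ones(p)
    Z = (X_train - mean) / scale

    gamma = config.resolve_gamma(p)
    sk = _SkSVR(
        kernel={"rbf": "rbf", "polynomial": "poly", "sigmoid": "sigmoid"}[config.kernel],
        C=config.C,
        epsilon=config.epsilon,
        gamma=gamma,
        degree=config.degree,
        coef0=config.coef0,
        tol=config.tol,
        cache_size=64,
    )
    sk.fit(Z, y_train)
    return SVRModel(
        config=config,
        support_vectors=np.asarray(sk.support_vectors_, float),
        dual_coef=np.asarray(sk.dual_coef_, float).ravel(),
        bias=float(np.asarray(sk.intercept_).ravel()[0]),
        gamma=gamma,
        x_mean=mean,
        x_scale=scale,
        descriptor_names=list(descriptor_names) if descriptor_names else None,
        passthrough_columns=passthrough,
    )


def predict(model: SVRModel, X_query: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = sum_i a_i K(s_i, x) + b on standardized coordinates."""
    X_query = np.asarray(X_query, dtype=float)
    if X_query.ndim == 1:
        X_query = X_query[None, :]
    if X_query.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"query has {X_query.shape[1]} columns, model expects "
            f"{model.support_vectors.shape[1]}"
        )
    Z = model.standardize(X_query)
    K = _kernel_matrix(Z, model.support_vectors, model.config, model.gamma)
    return K @ model.dual_coef + model.bias
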