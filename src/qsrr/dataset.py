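"""Data model and I/O for QSRR descriptor tables.

A QSRR (quantitative structure-retention relationship) dataset is a numeric
descriptor matrix ``X`` (one row per observation -- a compound measured under
one chromatographic condition), a response vector ``y`` of retention factors
``k``, and a train/test assignment.  Retention factors are dimensionless,

    k = (t_R - t_0) / t_0,

with ``t_R`` the analyte retention time and ``t_0`` the column dead time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QSRRDataset",
    "PredictionTable",
    "compute_retention_factor",
    "load_dataset",
    "write_dataset",
    "filter_descriptors",
    "assign_split",
]

#: relative variance below which a descriptor column counts as constant
CONSTANT_VARIANCE_RTOL = 1e-12

TRAIN, TEST, UNASSIGNED = "train", "test", "unassigned"


class DatasetError(ValueError):
    """Raised for malformed descriptor tables or inconsistent datasets."""


@dataclass
class QSRRDataset:
    """Descriptor matrix + retention-factor response + split flags.

    Invariants (checked in ``__post_init__``): equal row counts everywhere,
    unique observation ids and descriptor names, finite values, k >= 0.
    """

    observation_ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray  # (n, p) float
    y: np.ndarray  # (n,) retention factors
    split: np.ndarray = field(default=None)  # (n,) str flags

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            self.X = self.X.reshape(len(self.observation_ids), -1)
        self.y = np.asarray(self.y, dtype=float)
        if self.split is None:
            self.split = np.full(len(self.y), UNASSIGNED, dtype=object)
        self.split = np.asarray(self.split, dtype=object)
        n = len(self.observation_ids)
        if not (self.X.shape[0] == len(self.y) == len(self.split) == n):
            raise DatasetError(
                f"inconsistent row counts: ids={n}, X={self.X.shape[0]}, "
                f"y={len(self.y)}, split={len(self.split)}"
            )
        if len(set(self.observation_ids)) != n:
            raise DatasetError("duplicate observation ids")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise DatasetError("duplicate descriptor names")
        if self.X.shape[1] != len(self.descriptor_names):
            raise DatasetError("descriptor_names do not match X columns")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise DatasetError(
                f"missing/non-finite descriptor value at row "
                f"{self.observation_ids[i]!r}, column {self.descriptor_names[j]!r}"
            )
        if not np.all(np.isfinite(self.y)):
            i = int(np.argwhere(~np.isfinite(self.y))[0])
            raise DatasetError(f"missing response at row {self.observation_ids[i]!r}")
        if np.any(self.y < 0):
            raise DatasetError("negative retention factor in response")

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == TRAIN

    @property
    def test_mask(self) -> np.ndarray:
        return self.split == TEST

    def subset(self, rows: np.ndarray) -> "QSRRDataset":
        rows = np.asarray(rows)
        return QSRRDataset(
            [self.observation_ids[i] for i in np.flatnonzero(rows)]
            if rows.dtype == bool
            else [self.observation_ids[i] for i in rows],
            list(self.descriptor_names),
            self.X[rows],
            self.y[rows],
            self.split[rows],
        )

    def select_descriptors(self, names: Sequence[str]) -> "QSRRDataset":
        """Column subset by descriptor name, preserving the given order."""
        idx = [self.descriptor_names.index(nm) for nm in names]
        return replace(
            self, descriptor_names=list(names), X=self.X[:, idx]
        )

    def to_frame(self, response_column: str = "k") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.descriptor_names)
        df.insert(0, "observation_id", self.observation_ids)
        df[response_column] = self.y
        df["split"] = self.split
        return df


@dataclass
class PredictionTable:
    """Experimental vs predicted retention factors for one fitted model.

    Prediction columns are NaN where not applicable (CV/calibration entries on
    test rows, external-test entries on training rows).  Residual convention:
    residual = predicted - experimental.
    """

    observation_ids: list[str]
    split: np.ndarray
    y_experimental: np.ndarray
    y_predicted_train: np.ndarray  # calibration (training-set) predictions
    y_predicted_cv: np.ndarray
    y_predicted_test: np.ndarray

    def __post_init__(self) -> None:
        self.split = np.asarray(self.split, dtype=object)
        for name in ("y_experimental", "y_predicted_train", "y_predicted_cv",
                     "y_predicted_test"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == TRAIN

    @property
    def test_mask(self) -> np.ndarray:
        return self.split == TEST

    def residuals(self, which: str) -> np.ndarray:
        """Residuals (predicted - experimental) of one prediction column.

        ``which`` is one of ``"train"``, ``"cv"``, ``"test"``; NaN rows
        (not-applicable entries) are dropped.
        """
        pred = {
            "train": self.y_predicted_train,
            "cv": self.y_predicted_cv,
            "test": self.y_predicted_test,
        }[which]
        ok = ~np.isnan(pred)
        return pred[ok] - self.y_experimental[ok]

    def pairs(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(observed, predicted) pairs where the requested column is populated."""
        pred = {
            "train": self.y_predicted_train,
            "cv": self.y_predicted_cv,
            "test": self.y_predicted_test,
        }[which]
        ok = ~np.isnan(pred)
        return self.y_experimental[ok], pred[ok]


# ---------------------------------------------------------------------------
# retention-factor arithmetic


def compute_retention_factor(t_retention: float, t_dead: float) -> float:
    """Retention factor k = (t_R - t_0)/t_0 (dimensionless).

    Raises ``ValueError`` when t_retention < t_dead (analyte apparently eluting
    before an unretained marker signals a mis-specified dead time).
    """
    if t_dead <= 0:
        raise ValueError(f"dead time must be positive, got {t_dead}")
    if t_retention < t_dead:
        raise ValueError(
            f"retention time {t_retention} min is below the dead time "
            f"{t_dead} min: analyte unretained or dead time mis-specified"
        )
    return (t_retention - t_dead) / t_dead


# ---------------------------------------------------------------------------
# I/O


def load_dataset(
    path: str | Path,
    response_column: str = "k",
    id_columns: Sequence[str] = ("observation_id",),
    split_column: str | None = "split",
) -> QSRRDataset:
    """Load a delimited descriptor table (CSV/TSV, '#' comments allowed).

    Observation ids are the id columns joined with ``@`` (e.g.
    ``Norfloxacin@pH6.5``); every remaining non-id, non-split column except the
    response is treated as a numeric descriptor.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if response_column not in df.columns:
        raise DatasetError(f"response column {response_column!r} not in {path.name}")
    for col in id_columns:
        if col not in df.columns:
            raise DatasetError(f"id column {col!r} not in {path.name}")
    ids = (
        df[list(id_columns)].astype(str).agg("@".join, axis=1).tolist()
        if len(id_columns) > 1
        else df[id_columns[0]].astype(str).tolist()
    )
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetError(f"duplicate observation ids: {dupes[:5]}")
    drop = set(id_columns) | {response_column}
    split = None
    if split_column and split_column in df.columns:
        split = df[split_column].astype(object).to_numpy()
        drop.add(split_column)
    descriptor_names = [c for c in df.columns if c not in drop]
    for col in descriptor_names:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = ids[int(np.flatnonzero(bad)[0])]
            raise DatasetError(
                f"non-numeric descriptor cell at row {row!r}, column {col!r}"
            )
        if values.isna().any():
            row = ids[int(np.flatnonzero(values.isna())[0])]
            raise DatasetError(f"missing value at row {row!r}, column {col!r}")
        df[col] = values
    y = pd.to_numeric(df[response_column], errors="coerce")
    if y.isna().any():
        row = ids[int(np.flatnonzero(y.isna())[0])]
        raise DatasetError(f"missing response at row {row!r}")
    X = df[descriptor_names].to_numpy(dtype=float) if descriptor_names else \
        np.empty((len(ids), 0))
    return QSRRDataset(ids, descriptor_names, X, y.to_numpy(dtype=float), split)


def write_dataset(
    dataset: QSRRDataset,
    path: str | Path,
    response_column: str = "k",
    float_format: str = "%.10g",
) -> None:
    """Write a dataset back to CSV in a form ``load_dataset`` round-trips."""
    df = dataset.to_frame(response_column)
    df.to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# descriptor filtering


def filter_descriptors(
    dataset: QSRRDataset, rtol: float = CONSTANT_VARIANCE_RTOL
) -> tuple[QSRRDataset, list[tuple[str, str]]]:
    """Drop all-zero and constant descriptor columns.

    A column is constant when its variance is below ``rtol`` times the squared
    column scale (max(1, max|x|)^2) -- a float-safe reading of "no variation".
    Returns the reduced dataset and a removal log of (name, reason) pairs.
    """
    if dataset.p < 1:
        raise DatasetError("dataset has no descriptors to filter")
    keep: list[int] = []
    log: list[tuple[str, str]] = []
    for j, name in enumerate(dataset.descriptor_names):
        col = dataset.X[:, j]
        if np.all(col == 0.0):
            log.append((name, "all-zero"))
            continue
        scale = max(1.0, float(np.max(np.abs(col))))
        if np.var(col) <= rtol * scale * scale:
            log.append((name, "constant"))
            continue
        keep.append(j)
    if not keep:
        raise DatasetError("all descriptors removed by variance filter")
    reduced = replace(
        dataset,
        descriptor_names=[dataset.descriptor_names[j] for j in keep],
        X=dataset.X[:, keep],
    )
    return reduced, log


def assign_split(dataset: QSRRDataset, test_ids: Sequence[str]) -> QSRRDataset:
    """Flag the given observation ids as the external test set, the rest train."""
    unknown = [t for t in test_ids if t not in dataset.observation_ids]
    if unknown:
        raise DatasetError(f"unknown observation ids in test set: {unknown[:5]}")
    test = set(test_ids)
    split = np.array(
        [TEST if i in test else TRAIN for i in dataset.observation_ids],
        dtype=object,
    )
    return replace(dataset, split=split)
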