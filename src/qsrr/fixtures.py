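"""Loaders for the packaged retention-factor tables.

The package ships the published reversed-phase HPLC retention factors of the
two antibacterial families the pipeline was developed on -- 21 quinolone
major-microspecies observations (five mobile-phase pH values, dead time
2.9 min) and 39 sulfonamide observations (three acetonitrile percentages,
dead time 2.0 min) -- together with the experimental/predicted/CV prediction
tables of the original FFA-SVR models, including train/test membership.

The molecular-descriptor matrices behind those models (MOE molecular
mechanical descriptors) are proprietary and unpublished; only the retention
factors and model predictions are packaged.  Synthetic descriptor matrices
for end-to-end runs come from :mod:`qsrr.synthetic`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .dataset import PredictionTable, QSRRDataset, load_dataset

__all__ = [
    "fixture_path",
    "load_quinolone_k",
    "load_quinolone_k_grid",
    "load_sulfonamide_k",
    "load_quinolone_predictions",
    "load_sulfonamide_predictions",
]

QUINOLONE_DEAD_TIME_MIN = 2.9
SULFONAMIDE_DEAD_TIME_MIN = 2.0
#: final model sizes: (n_train, n_test, selected descriptors)
QUINOLONE_MODEL_SHAPE = (16, 5, 5)
SULFONAMIDE_MODEL_SHAPE = (30, 9, 3)  # 2 selected descriptors + ACN percentage


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    return Path(resources.files("qsrr.data") / name)


def load_quinolone_k() -> QSRRDataset:
    """The 21 modeled quinolone observations (id = compound@pH; p = 0)."""
    return load_dataset(
        fixture_path("quinolones_k.csv"),
        response_column="k",
        id_columns=("compound", "ph"),
    )


def load_quinolone_k_grid() -> pd.DataFrame:
    """Full 11-compound x 5-pH retention-factor grid (long format)."""
    wide = pd.read_csv(fixture_path("quinolones_k_grid.csv"), comment="#")
    long = wide.melt(id_vars="compound", var_name="ph", value_name="k")
    long["ph"] = long["ph"].str.removeprefix("ph").astype(float)
    return long.sort_values(["compound", "ph"], ignore_index=True)


def load_sulfonamide_k() -> QSRRDataset:
    """The 39 sulfonamide observations (id = compound@ACN percent; p = 0)."""
    return load_dataset(
        fixture_path("sulfonamides_k.csv"),
        response_column="k",
        id_columns=("compound", "acn_percent"),
    )


def _load_predictions(name: str, id_columns: tuple[str, str]) -> PredictionTable:
    df = pd.read_csv(fixture_path(name), comment="#")
    ids = df[list(id_columns)].astype(str).agg("@".join, axis=1).tolist()
    return PredictionTable(
        observation_ids=ids,
        split=df["split"].to_numpy(dtype=object),
        y_experimental=df["k_exp"].to_numpy(float),
        y_predicted_train=df["k_pred_cal"].to_numpy(float),
        y_predicted_cv=df["k_pred_cv"].to_numpy(float),
        y_predicted_test=df["k_pred_test"].to_numpy(float),
    )


def load_quinolone_predictions() -> PredictionTable:
    """Quinolone model predictions: 16 train (+LOO CV) and 5 test rows."""
    return _load_predictions("quinolones_predictions.csv", ("compound", "ph"))


def load_sulfonamide_predictions() -> PredictionTable:
    """Sulfonamide model predictions: 30 train (+leave-10%-out CV), 9 test."""
    return _load_predictions(
        "sulfonamides_predictions.csv", ("compound", "acn_percent")
    )
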