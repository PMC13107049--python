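"""Cell-table I/O, pipeline configuration and the end-to-end
identification workflow.

The interchange format is a headered CSV with one row per segmented cell
or flow event:

    cell_id, population (optional), x_um (optional), y_um (optional),
    ch_C, ch_G, ch_R, ch_ref (optional)

Arbitrary upstream headers are adapted through a column-mapping schema.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, features

__all__ = [
    "CellTableError",
    "PipelineConfig",
    "read_cell_table",
    "write_cell_table",
    "run_identification",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cell_id", "ch_C", "ch_G", "ch_R")
OPTIONAL_COLUMNS = ("population", "x_um", "y_um", "ch_ref")
INTENSITY_COLUMNS = ("ch_C", "ch_G", "ch_R", "ch_ref")


class CellTableError(ValueError):
    """Structured error for malformed cell tables."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one identification run."""

    channel_map: dict[str, str] = field(default_factory=dict)
    control_medians: dict[str, float] | None = None
    normalize: bool = True
    background_before_normalize: bool = True
    train_fraction: float = 0.8
    split_seed: int = 0
    covariance_regularization: float = 1e-6
    reliability_threshold: float = 0.95
    pairwise_seed: int = 0
    n_draws: int = 10_000_000
    panel_sizes: list[int] = field(default_factory=lambda: [20])
    area_mode: str = "given"
    n_shuffles: int = 100
    spatial_seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise CellTableError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)


def read_cell_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-cell intensity CSV, optionally renaming columns through
    ``schema`` (mapping source header → standard name).  Rows with
    non-numeric intensities are rejected with their line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise CellTableError(f"{path}: empty file") from e
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"{path}: missing required columns {missing}")
    present_intensities = [c for c in INTENSITY_COLUMNS if c in df.columns]
    bad_lines: list[int] = []
    for c in present_intensities:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        nonfinite = ~np.isfinite(vals.fillna(0.0).to_numpy())
        bad_rows = df.index[bad | df[c].isna() | pd.Series(nonfinite, index=df.index)]
        bad_lines.extend(int(i) + 2 for i in bad_rows)  # +2: header + 1-based
        df[c] = vals
    if bad_lines:
        raise CellTableError(
            f"{path}: non-numeric or non-finite intensities at lines {sorted(set(bad_lines))}"
        )
    df["cell_id"] = df["cell_id"].astype(str)
    return df


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, lineterminator="\r\n")


def prepare_features(
    table: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Background correction → global-median normalization → spherical angles."""
    out = table
    if config.control_medians and config.background_before_normalize:
        out = features.subtract_background(out, config.control_medians)
    if config.normalize:
        out = features.normalize_global_median(out)
    if config.control_medians and not config.background_before_normalize:
        out = features.subtract_background(out, config.control_medians)
    return features.add_spherical_features(out)


def run_identification(
    train_table: pd.DataFrame,
    target_table: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """End-to-end identification of a pooled sample.

    Fits the class-conditional mixture on the labeled training table
    (after its own train/test split for accuracy reporting), then assigns
    every target cell a population and a membership probability.

    Returns a dict with keys: ``model``, ``train_accuracy``,
    ``confusion`` (train-side test split), ``predictions`` (per-cell
    DataFrame), ``high_reliability_fraction``, and — when the target table
    carries labels — ``target_accuracy`` and ``target_confusion``.
    """
    config = config or PipelineConfig()
    if "population" not in train_table.columns:
        raise CellTableError("training table must carry a 'population' column")
    train_feats = prepare_features(train_table, config)
    train_feats = train_feats[train_feats["valid"]]
    tr, te = classify.stratified_split(
        train_feats, config.train_fraction, seed=config.split_seed
    )
    model = classify.fit_class_conditional(
        tr, covariance_regularization=config.covariance_regularization
    )
    te_res = classify.posterior_membership(model, te)
    cm, train_acc, per_class = classify.confusion_and_accuracy(
        te["population"].tolist(), te_res.predicted.tolist(), labels=model.labels
    )

    target_feats = prepare_features(target_table, config)
    res = classify.posterior_membership(model, target_feats)
    preds = target_feats[["cell_id"]].copy() if "cell_id" in target_feats else pd.DataFrame()
    preds["predicted"] = res.predicted
    preds["max_posterior"] = res.max_posterior
    preds["valid"] = res.valid

    out = {
        "model": model,
        "train_accuracy": train_acc,
        "confusion": cm,
        "per_class_accuracy": per_class,
        "predictions": preds,
        "high_reliability_fraction": res.high_reliability_fraction(
            config.reliability_threshold
        ),
        "reliability_threshold": config.reliability_threshold,
    }
    if "population" in target_table.columns and target_table["population"].notna().all():
        mask = res.valid
        t_cm, t_acc, _ = classify.confusion_and_accuracy(
            target_feats.loc[mask, "population"].tolist(),
            res.predicted[mask].tolist(),
            labels=model.labels,
        )
        out["target_accuracy"] = t_acc
        out["target_confusion"] = t_cm
    return out
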