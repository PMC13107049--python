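"""Intensity preprocessing and angle featurization.

The classifier never sees raw intensities.  Channels are background
corrected, divided by their pooled (across all populations) medians, and
then collapsed to scale-free angles:

    r           = (x² + y² + z²)^½                    with x=ch_C, y=ch_G, z=ch_R
    angle_cvsg  = atan2(y, x)  in degrees             green vs. cyan balance
    angle_rvscg = arccos(z / r) in degrees            red vs. the cyan–green plane

Both angles lie in [0°, 90°] for nonnegative channels and are invariant
to a common positive rescaling of the three channels, so the per-cell
expression level drops out and only the copy-number ratio structure
remains.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "subtract_background",
    "normalize_global_median",
    "to_polar_angle",
    "to_spherical",
    "add_spherical_features",
    "relative_brightness",
]

logger = logging.getLogger(__name__)

CHANNELS = ("ch_C", "ch_G", "ch_R")
ANGLE_COLS = ("r", "angle_cvsg_deg", "angle_rvscg_deg")


def subtract_background(
    table: pd.DataFrame,
    control_medians: Mapping[str, float],
    channels: Sequence[str] = CHANNELS,
) -> pd.DataFrame:
    """Subtract per-channel control medians (non-fluorescent cells), clamping at 0."""
    missing = [c for c in channels if c not in control_medians]
    if missing:
        raise KeyError(f"control medians missing for channels: {missing}")
    out = table.copy()
    n_clamped = 0
    for c in channels:
        v = out[c].to_numpy(float) - float(control_medians[c])
        n_clamped += int(np.sum(v < 0))
        out[c] = np.clip(v, 0.0, None)
    if n_clamped:
        logger.info("subtract_background: clamped %d negative values to 0", n_clamped)
    return out


def normalize_global_median(
    table: pd.DataFrame, channels: Sequence[str] = CHANNELS
) -> pd.DataFrame:
    """Divide each channel by its pooled median over *all* cells combined.

    The median is taken across the union of populations, not per
    population, so relative level structure between populations survives.
    After the call each channel's pooled median is exactly 1.
    """
    out = table.copy()
    for c in channels:
        med = float(np.median(out[c].to_numpy(float)))
        if med <= 0:
            raise ValueError(f"channel {c!r} has non-positive pooled median {med}")
        out[c] = out[c] / med
    return out


def to_polar_angle(numerator, denominator):
    """Two-argument arctangent in degrees, in [0, 90] for nonnegative inputs.

    Encodes the intensity ratio numerator/denominator on an angular scale:
    0° when the numerator vanishes, 90° when the denominator vanishes, 45°
    at equality.  (0, 0) yields NaN — the invalid-feature marker — rather
    than raising.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    ang = np.degrees(np.arctan2(num, den))
    ang = np.where((num == 0) & (den == 0), np.nan, ang)
    if ang.ndim == 0:
        return float(ang)
    return ang


def to_spherical(ch_C, ch_G, ch_R) -> pd.DataFrame:
    """Spherical-coordinate features of nonnegative channel triples.

    Returns a DataFrame with columns ``r``, ``angle_cvsg_deg``,
    ``angle_rvscg_deg`` and ``valid``.  r = 0 (an all-dark cell) is flagged
    invalid with NaN angles.  When ch_C = ch_G = 0 but ch_R > 0 the
    in-plane angle is taken as 0° by convention (the red-vs-plane angle
    carries all information there).
    """
    x = np.asarray(ch_C, dtype=float)
    y = np.asarray(ch_G, dtype=float)
    z = np.asarray(ch_R, dtype=float)
    x, y, z = np.atleast_1d(x, y, z)
    r = np.sqrt(x**2 + y**2 + z**2)
    valid = r > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cvsg = np.degrees(np.arctan2(y, x))
        cvsg = np.where((x == 0) & (y == 0), 0.0, cvsg)
        # arccos(z/r) evaluated as atan2(hypot(x, y), z): same angle, but
        # well-conditioned near the red axis where z/r ≈ 1
        rvscg = np.degrees(np.arctan2(np.hypot(x, y), z))
    cvsg = np.where(valid, cvsg, np.nan)
    rvscg = np.where(valid, rvscg, np.nan)
    return pd.DataFrame(
        {"r": r, "angle_cvsg_deg": cvsg, "angle_rvscg_deg": rvscg, "valid": valid}
    )


def add_spherical_features(table: pd.DataFrame) -> pd.DataFrame:
    """Append the spherical features to a cell table (columns ch_C/ch_G/ch_R).

    Cells with r = 0 are kept but flagged ``valid=False``; the count is
    logged so dark cells are never silently dropped.
    """
    feats = to_spherical(
        table["ch_C"].to_numpy(), table["ch_G"].to_numpy(), table["ch_R"].to_numpy()
    )
    n_dark = int((~feats["valid"]).sum())
    if n_dark:
        logger.info("add_spherical_features: %d cells with r=0 flagged invalid", n_dark)
    out = table.reset_index(drop=True).copy()
    for c in feats.columns:
        out[c] = feats[c].to_numpy()
    return out


def relative_brightness(
    split_cells: pd.DataFrame,
    fulllength_cells: pd.DataFrame,
    signal_col: str = "ch_C",
    expression_col: str = "ch_ref",
    gate_col: str | None = None,
    gate_threshold: float = 0.0,
) -> pd.Series:
    """Per-cell brightness of a split-FP construct relative to the
    full-length protein.

    Three steps: (1) per-cell full-length/expression-marker ratios; their
    median is the normalization standard; (2) per gated split-FP cell, the
    split/expression-marker ratio; (3) each ratio divided by the standard.
    By construction the full-length population's own median relative
    brightness is exactly 1.

    ``gate_col``/``gate_threshold`` optionally restrict the split table to
    reporter-positive cells (e.g. cells verified to express the 1–10
    fragment) before step 2.
    """
    for df, name in ((split_cells, "split_cells"), (fulllength_cells, "fulllength_cells")):
        for col in (signal_col, expression_col):
            if col not in df.columns:
                raise KeyError(f"{name} lacks column {col!r}")
    full_ratio = (
        fulllength_cells[signal_col].to_numpy(float)
        / fulllength_cells[expression_col].to_numpy(float)
    )
    standard = float(np.median(full_ratio))
    if standard == 0:
        raise ValueError("degenerate reference: full-length ratio median is 0")
    gated = split_cells
    if gate_col is not None:
        gated = split_cells[split_cells[gate_col] > gate_threshold]
    if len(gated) == 0:
        raise ValueError("gate excluded every split-FP cell")
    split_ratio = gated[signal_col].to_numpy(float) / gated[expression_col].to_numpy(float)
    return pd.Series(split_ratio / standard, index=gated.index, name="relative_brightness")
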