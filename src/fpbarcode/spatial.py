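"""Spatial statistics for labeled cell-centroid patterns.

Two questions about a co-culture of labeled populations are addressed:

* Does a single population cluster with itself?  Answered by the
  Clark–Evans index R, the ratio of the observed mean nearest-neighbor
  distance to the expectation 0.5/sqrt(density) under complete spatial
  randomness (CSR).  R ≈ 1 random, R < 1 clustered, R > 1 regular.

* Which populations sit next to which?  Answered by tallying, for each
  cell of a target population, the single nearest cell belonging to any
  *other* population, and comparing those heterotypic counts to a null
  obtained by permuting labels over the fixed centroid positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "LabeledPointPattern",
    "ClarkEvansResult",
    "AdjacencyResult",
    "nn_distances",
    "clark_evans",
    "heterotypic_nn_counts",
    "nn_adjacency_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class LabeledPointPattern:
    """Cell centroids (μm), one population label per point, and the region area (μm²)."""

    points: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) str
    region_area: float
    region_polygon: np.ndarray | None = None  # optional (m, 2) vertices

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must have equal length")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.region_area <= 0:
            raise ValueError("region_area must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def label_set(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())

    def subset(self, label: str) -> np.ndarray:
        return self.points[self.labels == label]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [f"cell{i:06d}" for i in range(len(self))],
                "x_um": self.points[:, 0],
                "y_um": self.points[:, 1],
                "label": self.labels,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, region_area: float) -> "LabeledPointPattern":
        return cls(
            points=df[["x_um", "y_um"]].to_numpy(float),
            labels=df["label"].to_numpy(),
            region_area=region_area,
        )


@dataclass
class ClarkEvansResult:
    R: float
    observed_mean_nn: float
    expected_mean_nn: float
    n: int
    area: float
    area_mode: str
    edge_correction: str


@dataclass
class AdjacencyResult:
    """Observed heterotypic nearest-neighbor counts vs. a label-permutation null."""

    target_label: str
    observed: dict[str, int]
    null_mean: dict[str, float]
    ratio: dict[str, float]  # observed / null mean; NaN where null mean is 0
    p_value: dict[str, float]  # empirical two-sided-free: P(null >= observed)
    n_shuffles: int
    null_counts: pd.DataFrame = field(repr=False)  # per-shuffle counts, one row per shuffle


def nn_distances(
    pattern: LabeledPointPattern, subset: str | None = None
) -> np.ndarray:
    """Distance from each point to its closest other point (optionally
    within one label), computed with a k-d tree; identical to the all-pairs
    scan."""
    pts = pattern.points if subset is None else pattern.subset(subset)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for nearest-neighbor distances")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def _resolve_area(pts: np.ndarray, pattern: LabeledPointPattern, area_mode: str) -> float:
    if area_mode == "given":
        return float(pattern.region_area)
    if area_mode == "bounding_box":
        span = pts.max(axis=0) - pts.min(axis=0)
        area = float(span[0] * span[1])
    elif area_mode == "convex_hull":
        area = float(ConvexHull(pts).volume)  # 2-D: volume is the area
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    if area <= 0:
        raise ValueError(f"degenerate {area_mode} area")
    logger.info("clark_evans: area resolved by %s = %.6g", area_mode, area)
    return area


def _boundary_perimeter(pts: np.ndarray, pattern: LabeledPointPattern) -> float:
    if pattern.region_polygon is not None:
        poly = np.asarray(pattern.region_polygon, float)
        d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())
    span = pts.max(axis=0) - pts.min(axis=0)
    return float(2 * (span[0] + span[1]))


def clark_evans(
    pattern: LabeledPointPattern,
    label: str | None = None,
    edge_correction: str = "none",
    area_mode: str = "given",
) -> ClarkEvansResult:
    """Clark–Evans dispersion index for one label (or the whole pattern).

    R = mean observed nearest-neighbor distance / (0.5 / sqrt(rho)),
    rho = n / area.  With ``edge_correction="cumulative-boundary"`` the CSR
    expectation gains a perimeter term (0.0514 + 0.041/sqrt(n)) * P / n that
    compensates the positive bias of ignoring neighbors outside the window.
    """
    pts = pattern.points if label is None else pattern.subset(label)
    n = len(pts)
    if n < 2:
        raise ValueError(f"need ≥ 2 points of label {label!r}")
    area = _resolve_area(pts, pattern, area_mode)
    observed = float(np.mean(nn_distances_raw(pts)))
    rho = n / area
    expected = 0.5 / np.sqrt(rho)
    if edge_correction == "cumulative-boundary":
        perim = _boundary_perimeter(pts, pattern)
        expected = expected + (0.0514 + 0.041 / np.sqrt(n)) * perim / n
    elif edge_correction != "none":
        raise ValueError(f"unknown edge_correction {edge_correction!r}")
    return ClarkEvansResult(
        R=observed / expected,
        observed_mean_nn=observed,
        expected_mean_nn=float(expected),
        n=n,
        area=area,
        area_mode=area_mode,
        edge_correction=edge_correction,
    )


def nn_distances_raw(pts: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distances of a bare coordinate array."""
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def _hetero_counts(
    points: np.ndarray, labels: np.ndarray, target_label: str, other_labels: Sequence[str]
) -> dict[str, int]:
    target_pts = points[labels == target_label]
    mask_other = labels != target_label
    other_pts = points[mask_other]
    other_lab = labels[mask_other]
    tree = cKDTree(other_pts)
    _, idx = tree.query(target_pts, k=1)
    nearest = other_lab[idx]
    return {lab: int(np.sum(nearest == lab)) for lab in other_labels}


def heterotypic_nn_counts(
    pattern: LabeledPointPattern, target_label: str
) -> dict[str, int]:
    """For each target cell find the single nearest cell of any *other*
    population; return counts per non-target label (summing to the number
    of target cells)."""
    if target_label not in pattern.labels:
        raise ValueError(f"target label {target_label!r} not present")
    other_labels = [l for l in pattern.label_set if l != target_label]
    if not np.any(pattern.labels != target_label):
        raise ValueError("no non-target cells present")
    return _hetero_counts(pattern.points, pattern.labels, target_label, other_labels)


def nn_adjacency_ratio(
    pattern: LabeledPointPattern,
    target_label: str,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> AdjacencyResult:
    """Heterotypic nearest-neighbor adjacency ratio with a permutation null.

    Labels are permuted uniformly over the fixed centroid positions
    (preserving each population's total count), the heterotypic counts are
    re-tallied per shuffle, and each observed count is divided by its null
    mean.  A ratio > 1 means that population is the nearest heterotypic
    neighbor of the target more often than label exchange alone explains.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be ≥ 1")
    observed = heterotypic_nn_counts(pattern, target_label)
    other_labels = list(observed)
    rng = np.random.default_rng(seed)
    rows = []
    labels = pattern.labels.copy()
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        rows.append(_hetero_counts(pattern.points, perm, target_label, other_labels))
    null_counts = pd.DataFrame(rows, columns=other_labels)
    null_mean = null_counts.mean(axis=0).to_dict()
    ratio: dict[str, float] = {}
    pval: dict[str, float] = {}
    for lab in other_labels:
        mu = null_mean[lab]
        if mu == 0:
            ratio[lab] = float("nan")
            logger.warning("nn_adjacency_ratio: null mean 0 for label %s; ratio undefined", lab)
        else:
            ratio[lab] = observed[lab] / mu
        # empirical upper-tail p with add-one smoothing
        pval[lab] = float(
            (1 + np.sum(null_counts[lab].to_numpy() >= observed[lab])) / (1 + n_shuffles)
        )
    return AdjacencyResult(
        target_label=target_label,
        observed=observed,
        null_mean={k: float(v) for k, v in null_mean.items()},
        ratio=ratio,
        p_value=pval,
        n_shuffles=n_shuffles,
        null_counts=null_counts,
    )
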