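"""Discriminability-driven tag-panel selection.

How many of the library's populations can be used together?  The answer
is bottlenecked by the *hardest* pair: a panel is only as good as its
least separable pair of populations.  Accordingly:

1. Every unordered pair of populations is pooled and split by an
   unsupervised two-component Gaussian mixture (EM, no training labels);
   the fraction of cells grouped correctly under the better of the two
   cluster→population assignments is that pair's discriminability.
2. Random k-subsets are drawn many times (default 10⁷ to cover panels of
   20 out of 96, where exhaustive enumeration of ~2·10²⁰ subsets is
   impossible) and the subset maximizing the minimum within-subset
   pairwise accuracy is kept.
3. A brute-force enumerator provides the exact optimum on small
   instances as an oracle for the random search.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .classify import DEFAULT_FEATURES

__all__ = [
    "PairwiseAccuracyMatrix",
    "SubsetSearchResult",
    "pairwise_accuracy",
    "pairwise_matrix",
    "min_pairwise",
    "maxmin_random_search",
    "maxmin_exhaustive",
]

logger = logging.getLogger(__name__)


@dataclass
class PairwiseAccuracyMatrix:
    """Symmetric matrix of pairwise two-population separation accuracies."""

    labels: list[str]
    values: np.ndarray  # (K, K), diagonal NaN
    cell_counts: np.ndarray  # (K, K) ints, cells used per entry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        K = len(self.labels)
        if self.values.shape != (K, K):
            raise ValueError("matrix shape mismatch")
        off = ~np.eye(K, dtype=bool)
        vals = self.values[off]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("pairwise accuracies must lie in [0, 1]")
        if not np.allclose(self.values[off], self.values.T[off]):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="population")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairwiseAccuracyMatrix":
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy(float)
        np.fill_diagonal(vals, np.nan)
        return cls(labels=[str(c) for c in df.columns], values=vals,
                   cell_counts=np.zeros_like(vals, dtype=int))

    @classmethod
    def from_values(cls, labels: Sequence[str], values: np.ndarray) -> "PairwiseAccuracyMatrix":
        vals = np.asarray(values, float).copy()
        np.fill_diagonal(vals, np.nan)
        return cls(labels=list(labels), values=vals, cell_counts=np.zeros_like(vals, dtype=int))


@dataclass
class SubsetSearchResult:
    k: int
    subset: list[str]
    min_accuracy: float
    n_draws: int | None
    seed: int | None
    exhaustive: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def pairwise_accuracy(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    seed: int = 0,
    balance: bool = True,
    min_cells: int = 10,
    n_init: int = 5,
) -> float:
    """Separation accuracy of two populations under an unsupervised
    two-component Gaussian mixture.

    The populations are pooled (balanced by subsampling the larger to the
    smaller, so neither dominates the fit), EM is run from ``n_init``
    seeded k-means starts keeping the best likelihood, and the accuracy is
    the fraction of cells grouped with their own population under the
    better of the two cluster↔population assignments — hence ≈ 0.5 for
    indistinguishable populations and 1.0 for disjoint ones.  Symmetric in
    its arguments by construction.
    """
    Xa = cells_a[list(feature_names)].to_numpy(float)
    Xb = cells_b[list(feature_names)].to_numpy(float)
    if len(Xa) < min_cells or len(Xb) < min_cells:
        raise ValueError(f"need ≥ {min_cells} cells per population, got {len(Xa)}/{len(Xb)}")
    rng = np.random.default_rng(seed)
    if balance and len(Xa) != len(Xb):
        m = min(len(Xa), len(Xb))
        if len(Xa) > m:
            Xa = Xa[rng.choice(len(Xa), m, replace=False)]
        else:
            Xb = Xb[rng.choice(len(Xb), m, replace=False)]
    X = np.vstack([Xa, Xb])
    truth = np.concatenate([np.zeros(len(Xa), int), np.ones(len(Xb), int)])
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        init_params="kmeans",
        random_state=int(rng.integers(0, 2**31 - 1)),
        reg_covar=1e-6,
    )
    pred = gm.fit_predict(X)
    if not gm.converged_:
        raise RuntimeError("two-component EM failed to converge")
    acc = float(np.mean(pred == truth))
    return max(acc, 1.0 - acc)


def pairwise_matrix(
    populations: pd.DataFrame,
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    label_col: str = "population",
    seed: int = 0,
    **kwargs,
) -> PairwiseAccuracyMatrix:
    """``pairwise_accuracy`` over every unordered pair of populations in a
    labeled feature table; each entry computed once and mirrored."""
    groups = {str(lab): grp for lab, grp in populations.groupby(label_col, sort=True)}
    labels = list(groups)
    K = len(labels)
    if K < 2:
        raise ValueError("need at least 2 populations")
    values = np.full((K, K), np.nan)
    counts = np.zeros((K, K), dtype=int)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(K), 2):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        try:
            acc = pairwise_accuracy(
                groups[labels[i]], groups[labels[j]],
                feature_names=feature_names, seed=pair_seed, **kwargs,
            )
        except Exception as e:
            raise RuntimeError(f"pairwise accuracy failed for ({labels[i]}, {labels[j]})") from e
        values[i, j] = values[j, i] = acc
        n_used = 2 * min(len(groups[labels[i]]), len(groups[labels[j]]))
        counts[i, j] = counts[j, i] = n_used
        logger.debug("pairwise %s vs %s: %.4f", labels[i], labels[j], acc)
    return PairwiseAccuracyMatrix(labels=labels, values=values, cell_counts=counts)


def min_pairwise(matrix: PairwiseAccuracyMatrix, subset: Sequence[str]) -> float:
    """Minimum pairwise accuracy over all unordered pairs within ``subset``
    — the panel's worst-case discriminability."""
    idx = [matrix.labels.index(s) for s in subset]
    if len(idx) < 2:
        logger.warning("min_pairwise: subset of size %d, vacuous minimum 1.0", len(idx))
        return 1.0
    sub = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.min(sub[iu]))


def maxmin_random_search(
    matrix: PairwiseAccuracyMatrix,
    k: int,
    n_draws: int = 10_000_000,
    seed: int | None = None,
) -> SubsetSearchResult:
    """Random-sampling max–min panel search.

    Draws ``n_draws`` uniform k-subsets (without replacement within each
    draw, independently across draws) and returns the subset with the
    largest minimum within-subset pairwise accuracy.  Ties keep the first
    subset found.
    """
    K = len(matrix.labels)
    if not 2 <= k <= K:
        raise ValueError(f"k={k} out of range [2, {K}]")
    rng = np.random.default_rng(seed)
    vals = matrix.values
    best_val = -np.inf
    best_subset: np.ndarray | None = None
    # vectorized in batches: draw indices, gather pair minima
    batch = max(1, min(n_draws, 100_000))
    iu = np.triu_indices(k, 1)
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        # per-row permutation trick for sampling without replacement
        draws = np.argpartition(rng.random((b, K)), k - 1, axis=1)[:, :k]
        sub = vals[draws[:, :, None], draws[:, None, :]]  # (b, k, k)
        mins = np.nanmin(sub[:, iu[0], iu[1]], axis=1)
        i = int(np.argmax(mins))
        if mins[i] > best_val:
            best_val = float(mins[i])
            best_subset = draws[i]
        done += b
    assert best_subset is not None
    subset = sorted(matrix.labels[i] for i in best_subset)
    achieved = min_pairwise(matrix, subset)
    assert math.isclose(achieved, best_val, rel_tol=0, abs_tol=1e-12)
    return SubsetSearchResult(k=k, subset=subset, min_accuracy=achieved,
                              n_draws=n_draws, seed=seed)


def maxmin_exhaustive(
    matrix: PairwiseAccuracyMatrix,
    k: int,
    enumeration_cap: int = 2_000_000,
) -> SubsetSearchResult:
    """Exact max–min optimum by full enumeration of all k-subsets; refuses
    above ``enumeration_cap`` subsets."""
    K = len(matrix.labels)
    if not 2 <= k <= K:
        raise ValueError(f"k={k} out of range [2, {K}]")
    total = math.comb(K, k)
    if total > enumeration_cap:
        raise ValueError(f"C({K},{k}) = {total} exceeds enumeration cap {enumeration_cap}")
    vals = matrix.values
    best_val = -np.inf
    best: tuple[int, ...] | None = None
    for combo in combinations(range(K), k):
        idx = np.array(combo)
        sub = vals[np.ix_(idx, idx)]
        m = float(np.min(sub[np.triu_indices(k, 1)]))
        if m > best_val:
            best_val = m
            best = combo
    assert best is not None
    subset = sorted(matrix.labels[i] for i in best)
    return SubsetSearchResult(k=k, subset=subset, min_accuracy=best_val,
                              n_draws=None, seed=None, exhaustive=True)
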