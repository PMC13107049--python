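"""Supervised class-conditional Gaussian mixture classification.

One Gaussian is fitted per labeled population by moment matching (sample
mean and covariance — no expectation-maximization), and the components
are concatenated into a mixture.  A cell's membership probability for
class k is the normalized density

    P(k | x) = N(x | μ_k, Σ_k) / Σ_j N(x | μ_j, Σ_j)

with uniform class priors; the maximum posterior doubles as a per-cell
classification reliability score.  Densities are evaluated in log space
(Cholesky factors, max-subtraction) so cells hundreds of standard
deviations from every mean still normalize cleanly.

A k-means alternative with majority-vote cluster→population remapping is
provided for the unsupervised setting; the many-to-one vote implements
the merge of multiple clusters arising from one bimodal population.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "ClassConditionalMixture",
    "MembershipResult",
    "DEFAULT_FEATURES",
    "stratified_split",
    "fit_class_conditional",
    "posterior_membership",
    "confusion_and_accuracy",
    "sensitivity",
    "kmeans_classify",
]

logger = logging.getLogger(__name__)

#: Angle feature space used throughout the trichromatic workflow.
DEFAULT_FEATURES = ("angle_cvsg_deg", "angle_rvscg_deg")


@dataclass
class ClassConditionalMixture:
    """Per-population Gaussian parameters plus posterior machinery."""

    labels: list[str]
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    weights: np.ndarray  # (K,)
    feature_names: list[str]
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.covariances = np.asarray(self.covariances, float)
        self.weights = np.asarray(self.weights, float)
        K = len(self.labels)
        d = len(self.feature_names)
        if self.means.shape != (K, d) or self.covariances.shape != (K, d, d):
            raise ValueError("inconsistent shapes among labels/means/covariances")
        if self.weights.shape != (K,):
            raise ValueError("weights length must match labels")
        if abs(self.weights.sum() - 1.0) > 1e-12 or np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative and sum to 1")
        self._chol = []
        for lab, cov in zip(self.labels, self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance of class {lab!r} is not symmetric")
            try:
                self._chol.append(np.linalg.cholesky(cov))
            except np.linalg.LinAlgError as e:
                raise ValueError(f"covariance of class {lab!r} is not positive definite") from e

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log densities, shape (n, K)."""
        X = np.asarray(X, float)
        n, d = X.shape
        out = np.empty((n, self.n_classes))
        for k, (mu, L) in enumerate(zip(self.means, self._chol)):
            diff = X - mu
            sol = solve_triangular(L, diff.T, lower=True)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            out[:, k] = -0.5 * (maha + logdet + d * np.log(2 * np.pi))
        return out

    def to_json(self, path: str | Path) -> None:
        obj = {
            "labels": self.labels,
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "covariances_row_major": self.covariances.reshape(self.n_classes, -1).tolist(),
            "weights": self.weights.tolist(),
            "regularization": self.regularization,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassConditionalMixture":
        obj = json.loads(Path(path).read_text())
        K = len(obj["labels"])
        d = len(obj["feature_names"])
        return cls(
            labels=list(obj["labels"]),
            means=np.array(obj["means"], float),
            covariances=np.array(obj["covariances_row_major"], float).reshape(K, d, d),
            weights=np.array(obj["weights"], float),
            feature_names=list(obj["feature_names"]),
            regularization=float(obj.get("regularization", 0.0)),
        )


@dataclass
class MembershipResult:
    """Per-cell predictions, full posteriors and reliability scores."""

    labels: list[str]
    predicted: np.ndarray  # (n,) str; NaN-feature cells carry ""
    posteriors: np.ndarray  # (n, K); NaN rows for excluded cells
    max_posterior: np.ndarray  # (n,)
    valid: np.ndarray  # (n,) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predicted": self.predicted,
                "max_posterior": self.max_posterior,
                "valid": self.valid,
            }
        )

    def high_reliability_fraction(self, threshold: float = 0.95) -> float:
        """Fraction of valid cells whose top membership probability exceeds
        ``threshold`` (the reliability-index readout)."""
        mp = self.max_posterior[self.valid]
        if len(mp) == 0:
            raise ValueError("no valid cells")
        return float(np.mean(mp > threshold))


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int | None = None,
    label_col: str = "population",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population random split into train/test at ``train_fraction``
    (rounding toward train), disjoint and seed-reproducible."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label, grp in table.groupby(label_col, sort=True):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            raise ValueError(f"population {label!r} has fewer than 2 cells")
        perm = rng.permutation(idx)
        n_train = int(np.ceil(train_fraction * len(idx)))
        n_train = min(n_train, len(idx) - 1)  # keep test non-empty
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (
        table.loc[np.concatenate(train_idx)].copy(),
        table.loc[np.concatenate(test_idx)].copy(),
    )


def fit_class_conditional(
    train: pd.DataFrame,
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    label_col: str = "population",
    covariance_regularization: float = 1e-6,
) -> ClassConditionalMixture:
    """Fit one Gaussian per population by moment matching.

    μ_k is the class sample mean, Σ_k the class sample covariance plus
    ``covariance_regularization``·I (so single-point or degenerate classes
    survive), and priors are uniform.  This is supervised: no EM runs.
    """
    if covariance_regularization < 0:
        raise ValueError("covariance_regularization must be nonnegative")
    labels: list[str] = []
    means, covs = [], []
    d = len(feature_names)
    for label, grp in train.groupby(label_col, sort=True):
        X = grp[list(feature_names)].to_numpy(float)
        if not np.all(np.isfinite(X)):
            raise ValueError(f"non-finite features in class {label!r}")
        mu = X.mean(axis=0)
        if len(X) > 1:
            cov = np.cov(X, rowvar=False).reshape(d, d)
        else:
            cov = np.zeros((d, d))
        cov = cov + covariance_regularization * np.eye(d)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as e:
            raise ValueError(
                f"covariance of class {label!r} singular even after regularization"
            ) from e
        labels.append(str(label))
        means.append(mu)
        covs.append(cov)
    K = len(labels)
    if K == 0:
        raise ValueError("no classes in training table")
    return ClassConditionalMixture(
        labels=labels,
        means=np.array(means),
        covariances=np.array(covs),
        weights=np.full(K, 1.0 / K),
        feature_names=list(feature_names),
        regularization=covariance_regularization,
    )


def posterior_membership(
    model: ClassConditionalMixture, cells: pd.DataFrame | np.ndarray
) -> MembershipResult:
    """Normalized membership probabilities and argmax labels per cell.

    Cells with non-finite features are flagged invalid (NaN posteriors,
    empty prediction) rather than dropped.  Ties go to the lowest class
    index and are logged.
    """
    if isinstance(cells, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in cells.columns]
        if missing:
            raise KeyError(f"feature columns missing: {missing}")
        X = cells[model.feature_names].to_numpy(float)
    else:
        X = np.asarray(cells, float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError("feature dimension mismatch")
    n = len(X)
    valid = np.all(np.isfinite(X), axis=1)
    if not np.all(valid):
        logger.info("posterior_membership: %d cells with non-finite features flagged", int((~valid).sum()))
    K = model.n_classes
    post = np.full((n, K), np.nan)
    if valid.any():
        logd = model.log_density(X[valid]) + np.log(model.weights)[None, :]
        logz = logsumexp(logd, axis=1, keepdims=True)
        post[valid] = np.exp(logd - logz)
    pred_idx = np.zeros(n, dtype=int)
    if valid.any():
        pred_idx[valid] = np.nanargmax(post[valid], axis=1)
        ties = np.sum(np.isclose(post[valid], post[valid].max(axis=1, keepdims=True)), axis=1) > 1
        if ties.any():
            logger.info("posterior_membership: %d posterior ties broken by class index", int(ties.sum()))
    predicted = np.where(valid, np.array(model.labels, dtype=object)[pred_idx], "")
    max_post = np.where(valid, np.nanmax(np.where(np.isnan(post), -np.inf, post), axis=1), np.nan)
    return MembershipResult(
        labels=list(model.labels),
        predicted=predicted.astype(object),
        posteriors=post,
        max_posterior=max_post,
        valid=valid,
    )


def confusion_and_accuracy(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float, pd.Series]:
    """Row-normalized confusion matrix (rows = true), pooled overall
    accuracy, and per-class accuracies.

    The pooled accuracy is the mean per-cell correctness; the macro
    average (mean of per-class accuracies) is the per-class Series' mean.
    """
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError("label sequences differ in length")
    if labels is None:
        labels = sorted(set(t.tolist()))
    labels = list(labels)
    unknown = set(t.tolist()) | set(p.tolist())
    if not unknown <= set(labels):
        raise ValueError(f"labels outside the model's label set: {sorted(unknown - set(labels))}")
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for ti, pi in zip(t, p):
        counts[idx[ti], idx[pi]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, np.nan)
    cm = pd.DataFrame(norm, index=labels, columns=labels)
    overall = float(np.mean(t == p))
    per_class = pd.Series(np.diag(norm), index=labels, name="accuracy")
    return cm, overall, per_class


def sensitivity(true_positive_count: int, ground_truth_count: int) -> float:
    """True positives over ground-truth positives, as a percentage."""
    if ground_truth_count <= 0:
        raise ValueError("ground_truth_count must be positive")
    if not 0 <= true_positive_count <= ground_truth_count:
        raise ValueError("need 0 ≤ TP ≤ ground truth")
    return 100.0 * true_positive_count / ground_truth_count


def majority_vote_mapping(
    cluster_ids: np.ndarray, reference_labels: np.ndarray
) -> dict[int, str]:
    """Map each cluster to the reference population holding the majority of
    its members (many-to-one; ties go to the lexicographically first label)."""
    mapping: dict[int, str] = {}
    for c in np.unique(cluster_ids):
        labs, counts = np.unique(reference_labels[cluster_ids == c], return_counts=True)
        order = np.lexsort((labs, -counts))
        mapping[int(c)] = str(labs[order[0]])
    return mapping


def kmeans_classify(
    features: pd.DataFrame,
    n_clusters: int,
    reference_labels: Sequence[str],
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    seed: int = 0,
    max_retries: int = 3,
) -> tuple[np.ndarray, float, dict[int, str]]:
    """Unsupervised k-means in angle space, remapped to populations by
    majority vote.

    Using more clusters than populations lets a bimodal population occupy
    two clusters that the many-to-one vote then merges.  Returns
    (remapped predictions, pooled accuracy, cluster→label mapping).
    """
    ref = np.asarray(reference_labels, dtype=object)
    n_pops = len(np.unique(ref))
    if n_clusters < n_pops:
        raise ValueError(f"n_clusters={n_clusters} < number of populations {n_pops}")
    X = features[list(feature_names)].to_numpy(float)
    for attempt in range(max_retries + 1):
        km = KMeans(n_clusters=n_clusters, random_state=seed + attempt, n_init=10)
        clusters = km.fit_predict(X)
        if len(np.unique(clusters)) == n_clusters:
            break
        logger.warning("kmeans_classify: empty cluster, re-seeding (attempt %d)", attempt + 1)
    else:
        raise RuntimeError("k-means produced an empty cluster after retries")
    mapping = majority_vote_mapping(clusters, ref)
    predicted = np.array([mapping[int(c)] for c in clusters], dtype=object)
    accuracy = float(np.mean(predicted == ref))
    return predicted, accuracy, mapping
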