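"""Membership-based activity scoring against a non-activity control cluster.

Each test segment's feature-variability vector is compared to the cluster of
zero-activity (control) segments with six criteria:

* ``euclidean``  — distance to the control centroid
* ``silhouette`` — two-cluster silhouette with the test point as a singleton
* ``cosine``     — cosine similarity to the control centroid
* ``knn``        — mean distance to the k nearest control members
* ``cms``        — cluster membership strength, 1/(mean distance + eps)
* ``gaussian``   — fuzzy Gaussian membership exp(-d^2 / 2 sigma^2)

Raw scores keep each criterion's native orientation; the *activity* score
flips similarity-like criteria so that higher always means less resemblance
to the control cluster, i.e. more bowel activity.  Features are jointly
z-scored (control + test pooled) before any distance is taken.

Note the built-in redundancy: the Gaussian membership is a fixed monotone
transform of the centroid distance, so its ranking is exactly the reverse of
the Euclidean ranking for any sigma; and CMS at k = N is the reciprocal of
the KNN grade (plus eps).  Both identities are exercised in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError, InvalidInputError, UndefinedScoreError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("euclidean", "silhouette", "cosine", "knn", "cms", "gaussian")

#: Sign applied to the raw score to obtain the activity score
#: (+1: raw already grows with activity; -1: raw grows with control likeness).
ORIENTATION = {
    "euclidean": +1.0,
    "silhouette": -1.0,
    "cosine": -1.0,
    "knn": +1.0,
    "cms": -1.0,
    "gaussian": -1.0,
}


@dataclass
class ControlCluster:
    """Z-scored feature vectors of the zero-activity segments."""

    members: np.ndarray                 # (N, p)
    centroid: np.ndarray = field(init=False)
    feature_std: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=np.float64))
        if self.members.shape[0] < 2:
            raise InvalidInputError("control cluster needs at least 2 members")
        self.centroid = self.members.mean(axis=0)
        self.feature_std = self.members.std(axis=0, ddof=1)

    @property
    def n(self) -> int:
        return self.members.shape[0]


@dataclass
class MetricConfig:
    """Tunables: k neighbours for KNN, eps guard for CMS, Gaussian sigma.

    sigma=None means "derive from the control cluster" (RMS of the
    per-feature stds — close to 1 after z-scoring).  Any positive sigma
    yields the same Gaussian ranking, so this choice affects the score
    scale only.  silhouette_singleton_only switches the silhouette to the
    test point's own score instead of the all-points mean.
    """

    k: int = 5
    eps: float = 1e-12
    sigma: float | None = None
    silhouette_singleton_only: bool = False


@dataclass
class MembershipScores:
    """Raw and activity-oriented scores per test segment (rows align)."""

    raw: pd.DataFrame
    activity: pd.DataFrame
    config: MetricConfig
    feature_names: tuple[str, ...] = ()


def zscore_fit_transform(
    control: np.ndarray,
    tests: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> tuple[ControlCluster, np.ndarray, tuple[str, ...]]:
    """Jointly standardize control and test feature matrices.

    The mean and sample std per feature are fit on the pooled rows and
    applied to both matrices; zero-variance columns are dropped with a
    warning.  Returns the standardized control cluster, the standardized
    test matrix, and the surviving feature names.
    """
    control = np.atleast_2d(np.asarray(control, dtype=np.float64))
    tests = np.atleast_2d(np.asarray(tests, dtype=np.float64))
    if control.shape[0] < 2:
        raise InvalidInputError("need at least 2 control rows to standardize")
    if control.shape[1] != tests.shape[1]:
        raise InvalidArgumentError("control and test matrices disagree in feature count")
    names = tuple(feature_names) if feature_names else tuple(
        f"f{j}" for j in range(control.shape[1])
    )
    pooled = np.vstack([control, tests]) if tests.size else control
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise InvalidInputError("all feature columns have zero variance")
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.warning("dropping zero-variance feature columns: %s", dropped)
    zc = (control[:, keep] - mu[keep]) / sd[keep]
    zt = (tests[:, keep] - mu[keep]) / sd[keep] if tests.size else tests[:, keep]
    return ControlCluster(zc), zt, tuple(n for n, k in zip(names, keep) if k)


def euclidean_to_centroid(x: np.ndarray, c: ControlCluster) -> float:
    """Straight-line distance from a test vector to the control centroid."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != c.centroid.shape:
        raise InvalidArgumentError(
            f"dimension mismatch: x has {x.shape}, centroid has {c.centroid.shape}"
        )
    return float(np.linalg.norm(x - c.centroid))


def silhouette_singleton(
    x: np.ndarray, c: ControlCluster, singleton_only: bool = False
) -> float:
    """Two-cluster silhouette of {x} versus the control cluster.

    The test point forms a singleton cluster whose own silhouette is 0 by
    convention (it has no intra-cluster distance).  Every control member
    contributes (b - a)/max(a, b) with a = mean distance to the other
    controls and b = its distance to x.  The returned score is the mean
    over all N+1 points (or the singleton's own score if requested, which
    is constant and therefore rank-neutral).
    """
    x = np.asarray(x, dtype=np.float64)
    M = c.members
    if singleton_only:
        return 0.0
    d_to_x = np.linalg.norm(M - x, axis=1)
    pair = cdist(M, M)
    a = pair.sum(axis=1) / (c.n - 1)          # mean distance to *other* members
    denom = np.maximum(a, d_to_x)
    s = np.where(denom > 0, (d_to_x - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float((s.sum() + 0.0) / (c.n + 1))


def cosine_to_centroid(x: np.ndarray, c: ControlCluster) -> float:
    """Cosine of the angle between a test vector and the control centroid."""
    x = np.asarray(x, dtype=np.float64)
    nx = np.linalg.norm(x)
    nc = np.linalg.norm(c.centroid)
    if nx == 0 or nc == 0:
        raise UndefinedScoreError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(x, c.centroid) / (nx * nc))


def knn_grade(x: np.ndarray, c: ControlCluster, k: int) -> float:
    """Mean Euclidean distance to the k nearest control members.

    Ties at the k-th distance are broken by member index (stable sort).
    """
    if not (1 <= k <= c.n):
        raise InvalidArgumentError(f"k must be in [1, {c.n}], got {k}")
    d = np.linalg.norm(c.members - np.asarray(x, dtype=np.float64), axis=1)
    order = np.argsort(d, kind="stable")
    return float(d[order[:k]].mean())


def cluster_membership_strength(x: np.ndarray, c: ControlCluster, eps: float = 1e-12) -> float:
    """Inverse of the mean distance to all control members (+ eps guard)."""
    if eps <= 0:
        raise InvalidArgumentError(f"eps must be positive, got {eps}")
    d = np.linalg.norm(c.members - np.asarray(x, dtype=np.float64), axis=1)
    return float(1.0 / (d.mean() + eps))


def default_sigma(c: ControlCluster) -> float:
    """RMS of the control per-feature stds; ~1 after z-scoring."""
    s = float(np.sqrt(np.mean(c.feature_std**2)))
    return s if s > 0 else 1.0


def gaussian_membership(x: np.ndarray, c: ControlCluster, sigma: float | None = None) -> float:
    """Fuzzy membership exp(-d^2 / (2 sigma^2)), d = distance to centroid."""
    if sigma is None:
        sigma = default_sigma(c)
    if sigma <= 0:
        raise InvalidArgumentError(f"sigma must be positive, got {sigma}")
    d = euclidean_to_centroid(x, c)
    return float(np.exp(-(d**2) / (2.0 * sigma**2)))


def grade_segments(
    tests: np.ndarray,
    control: ControlCluster,
    config: MetricConfig | None = None,
    feature_names: tuple[str, ...] = (),
) -> MembershipScores:
    """Score every test vector with all six criteria.

    Inputs are expected to be already standardized (see
    :func:`zscore_fit_transform`).  Rows of the returned frames align with
    the rows of ``tests``; segments whose cosine similarity is undefined
    (zero-norm vector) get NaN for that metric and a warning.
    """
    cfg = config or MetricConfig()
    tests = np.atleast_2d(np.asarray(tests, dtype=np.float64))
    sigma = cfg.sigma if cfg.sigma is not None else default_sigma(control)
    rows = []
    for i, x in enumerate(tests):
        try:
            cos = cosine_to_centroid(x, control)
        except UndefinedScoreError:
            logger.warning("test row %d has zero norm; cosine similarity undefined", i)
            cos = np.nan
        rows.append({
            "euclidean": euclidean_to_centroid(x, control),
            "silhouette": silhouette_singleton(
                x, control, singleton_only=cfg.silhouette_singleton_only
            ),
            "cosine": cos,
            "knn": knn_grade(x, control, cfg.k),
            "cms": cluster_membership_strength(x, control, cfg.eps),
            "gaussian": gaussian_membership(x, control, sigma),
        })
    raw = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    activity = raw * pd.Series(ORIENTATION)
    return MembershipScores(raw=raw, activity=activity, config=cfg, feature_names=feature_names)
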