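"""Ground-truth activity percentages and Spearman rank evaluation.

The ground truth for a segment is the percentage of its duration covered by
annotated bowel-sound intervals.  A grading criterion is judged by the
Spearman rank correlation rho between its activity-oriented scores and the
true activity percentages over a stratified test set: segments above an
activity threshold are tests, zero-activity segments are controls, and
segments in between are excluded (they are neither clearly active nor
clean reference material).

rho is computed as the Pearson correlation of tie-averaged ranks, which
reduces to the classical 1 - 6*sum(d_i^2)/(n(n^2-1)) formula when there are
no ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidArgumentError, InvalidInputError, UndefinedScoreError
from .signal_ingest import ActivityAnnotation, Segment


@dataclass
class GradingEvaluation:
    """Spearman evaluation of one metric on one stratified subset."""

    rho: float | None
    abs_rho: float | None
    n: int
    metric: str = ""
    feature_subset: tuple[str, ...] = ()
    threshold_pct: float = 0.0
    undefined: bool = False


def activity_percentage(seg: Segment, ann: ActivityAnnotation | None) -> float:
    """Percent of the segment's [start, start+duration) covered by activity.

    Overlapping annotation intervals are merged first, so the result is the
    coverage of their union and never exceeds 100.
    """
    if ann is None or not ann.intervals:
        return 0.0
    lo, hi = seg.start_time, seg.start_time + seg.duration
    covered = sum(
        max(0.0, min(e, hi) - max(s, lo)) for s, e in ann.merged()
    )
    return 100.0 * covered / seg.duration


def stratify_subset(
    truth: pd.DataFrame, threshold_pct: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split segment indices into tests (> threshold) and controls (== 0).

    ``truth`` needs an ``activity_pct`` column; segments with activity in
    (0, threshold] belong to neither group.  Returns (test_idx, control_idx)
    as positional indices into ``truth``.
    """
    if not (0.0 <= threshold_pct < 100.0):
        raise InvalidArgumentError(f"threshold must be in [0, 100), got {threshold_pct}")
    act = np.asarray(truth["activity_pct"], dtype=np.float64)
    test_idx = np.flatnonzero(act > threshold_pct)
    control_idx = np.flatnonzero(act == 0.0)
    if test_idx.size == 0:
        raise InvalidInputError(f"no test segments above {threshold_pct}% activity")
    if control_idx.size == 0:
        raise InvalidInputError("no zero-activity control segments")
    return test_idx, control_idx


def rank_with_ties(values: np.ndarray) -> np.ndarray:
    """Fractional (average) ranks, 1-based; ranks sum to n(n+1)/2."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise InvalidInputError("cannot rank an empty sequence")
    return rankdata(values, method="average")


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation of two value sequences (ties averaged).

    Equivalent to the closed form 1 - 6*sum(d^2)/(n(n^2-1)) when all values
    are distinct.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidArgumentError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 observations")
    rx = rank_with_ties(x)
    ry = rank_with_ties(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedScoreError("rank correlation undefined: all ranks tied")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def evaluate_grading(
    activity_scores: np.ndarray,
    activity_pct: np.ndarray,
    metric: str = "",
    feature_subset: tuple[str, ...] = (),
    threshold_pct: float = 0.0,
) -> GradingEvaluation:
    """Spearman rho between oriented activity scores and true percentages.

    Inputs are aligned over the already-stratified test segments.  A
    degenerate case (all scores tied) is reported as a flagged null
    result rather than a numeric rho.
    """
    activity_scores = np.asarray(activity_scores, dtype=np.float64)
    activity_pct = np.asarray(activity_pct, dtype=np.float64)
    try:
        rho = spearman_rho(activity_scores, activity_pct)
    except UndefinedScoreError:
        return GradingEvaluation(
            rho=None, abs_rho=None, n=activity_scores.size, metric=metric,
            feature_subset=tuple(feature_subset), threshold_pct=threshold_pct,
            undefined=True,
        )
    return GradingEvaluation(
        rho=rho, abs_rho=abs(rho), n=activity_scores.size, metric=metric,
        feature_subset=tuple(feature_subset), threshold_pct=threshold_pct,
    )
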