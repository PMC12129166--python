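"""Greedy forward selection of the spectral-feature subset.

Starting from the empty set, each remaining feature is tried in turn and
the one giving the largest Spearman rho is added — but only if it strictly
improves on the current best; the search stops otherwise.  Candidate ties
are broken by canonical feature order, so traces are fully reproducible.
An exhaustive enumerator over all non-empty subsets serves as a
verification oracle for small feature counts.

This search is a tuning harness for experiments, not part of the runtime
grading path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from . import membership_metrics, pipeline
from .errors import InvalidArgumentError
from .spectral_features import FEATURE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Target and grading parameters for the subset search."""

    threshold_pct: float = 30.0
    use_abs: bool = False
    metric_config: membership_metrics.MetricConfig = field(
        default_factory=membership_metrics.MetricConfig
    )
    max_reasonable_subset: int = 6


@dataclass
class SelectionTrace:
    """Ordered record of the greedy search."""

    steps: list[tuple[str, float]]
    final_subset: tuple[str, ...]
    final_score: float
    metric: str


def _score_subset(
    features: pd.DataFrame, metric: str, subset: tuple[str, ...], cfg: SelectionConfig
) -> float | None:
    try:
        res = pipeline.grade_and_evaluate(
            features, metric, cfg.threshold_pct,
            feature_subset=subset, config=cfg.metric_config, use_abs=cfg.use_abs,
        )
    except Exception as exc:
        logger.warning("subset %s failed evaluation: %s", subset, exc)
        return None
    return res.rho  # None when rho is undefined (all scores tied)


def greedy_forward_select(
    features: pd.DataFrame,
    metric: str,
    config: SelectionConfig | None = None,
    candidates: tuple[str, ...] = FEATURE_NAMES,
) -> SelectionTrace:
    """Grow the feature subset one best-improving feature at a time."""
    cfg = config or SelectionConfig()
    if not candidates:
        raise InvalidArgumentError("need at least one candidate feature")
    selected: list[str] = []
    steps: list[tuple[str, float]] = []
    best = float("-inf")
    remaining = [f for f in FEATURE_NAMES if f in candidates]

    while remaining:
        round_best_feature = None
        round_best_score = best
        for feat in remaining:  # canonical order => deterministic tie-break
            score = _score_subset(features, metric, tuple(selected + [feat]), cfg)
            if score is not None and score > round_best_score:
                round_best_score = score
                round_best_feature = feat
        if round_best_feature is None:
            break
        selected.append(round_best_feature)
        remaining.remove(round_best_feature)
        best = round_best_score
        steps.append((round_best_feature, best))

    if len(selected) > cfg.max_reasonable_subset:
        logger.warning(
            "greedy selection kept %d features; subsets this large are unusual",
            len(selected),
        )
    return SelectionTrace(
        steps=steps, final_subset=tuple(selected), final_score=best, metric=metric
    )


def exhaustive_select(
    features: pd.DataFrame,
    metric: str,
    config: SelectionConfig | None = None,
    candidates: tuple[str, ...] = FEATURE_NAMES,
    max_features: int | None = None,
) -> tuple[tuple[str, ...], float]:
    """Best subset by full enumeration; only feasible for few candidates."""
    cfg = config or SelectionConfig()
    cand = [f for f in FEATURE_NAMES if f in candidates]
    if len(cand) > 12:
        raise InvalidArgumentError(f"{len(cand)} candidates is too many to enumerate")
    limit = max_features or len(cand)
    best_subset: tuple[str, ...] = ()
    best_score = float("-inf")
    for r in range(1, limit + 1):
        for subset in combinations(cand, r):
            score = _score_subset(features, metric, subset, cfg)
            if score is not None and score > best_score:
                best_score = score
                best_subset = subset
    return best_subset, best_score
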