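"""Glue between feature tables and the grading/evaluation stages.

A *feature table* is a DataFrame with ``source_id``, ``start_s``,
``activity_pct`` and the 11 canonical feature columns — the same schema the
feature CSV uses on disk.
"""

from __future__ import annotations

import pandas as pd

from . import evaluation, membership_metrics, signal_ingest
from .errors import InvalidArgumentError
from .spectral_features import FEATURE_NAMES, FeatureConfig, extract_segment_vector

META_COLUMNS = ("source_id", "start_s", "activity_pct")


def extract_feature_table(
    recordings: list[signal_ingest.AudioRecording],
    annotations: list[signal_ingest.ActivityAnnotation],
    band: tuple[float, float] = signal_ingest.DEFAULT_BAND,
    seg_len: float = signal_ingest.DEFAULT_SEGMENT_LEN,
    feature_config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Band-pass, segment and featurize recordings into a feature table.

    Each segment contributes one row: provenance, its ground-truth activity
    percentage (from the matching annotation, if any), and the 11 feature
    stds.
    """
    ann_by_id = {a.source_id: a for a in annotations}
    rows = []
    for rec in recordings:
        filtered = signal_ingest.bandpass(rec, *band)
        for seg in signal_ingest.segment_fixed(filtered, seg_len):
            vec = extract_segment_vector(seg, feature_config)
            row = {
                "source_id": seg.source_id,
                "start_s": seg.start_time,
                "activity_pct": evaluation.activity_percentage(
                    seg, ann_by_id.get(seg.source_id)
                ),
            }
            row.update(dict(zip(FEATURE_NAMES, vec.values)))
            rows.append(row)
    return pd.DataFrame(rows, columns=[*META_COLUMNS, *FEATURE_NAMES])


def validate_feature_table(features: pd.DataFrame, subset: tuple[str, ...]) -> None:
    missing = [c for c in ("activity_pct", *subset) if c not in features.columns]
    if missing:
        raise InvalidArgumentError(f"feature table missing columns: {missing}")


def grade_and_evaluate(
    features: pd.DataFrame,
    metric: str,
    threshold_pct: float,
    feature_subset: tuple[str, ...] | None = None,
    config: membership_metrics.MetricConfig | None = None,
    use_abs: bool = False,
) -> evaluation.GradingEvaluation:
    """Stratify, z-score, grade with one metric, and evaluate by Spearman rho.

    ``use_abs`` makes the returned ``rho`` field carry |rho| (useful as a
    selection target when a criterion's orientation is unstable).
    """
    if metric not in membership_metrics.METRIC_NAMES:
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    if feature_subset:
        subset = tuple(feature_subset)
    else:  # default to every canonical feature the table carries
        subset = tuple(f for f in FEATURE_NAMES if f in features.columns)
    bad = [f for f in subset if f not in FEATURE_NAMES]
    if bad:
        raise InvalidArgumentError(f"unknown features: {bad}")
    validate_feature_table(features, subset)

    test_idx, control_idx = evaluation.stratify_subset(features, threshold_pct)
    control = features.iloc[control_idx][list(subset)].to_numpy()
    tests = features.iloc[test_idx][list(subset)].to_numpy()
    cluster, ztests, kept = membership_metrics.zscore_fit_transform(control, tests, subset)
    cfg = config or membership_metrics.MetricConfig()
    if cfg.k > cluster.n:
        cfg = membership_metrics.MetricConfig(
            k=cluster.n, eps=cfg.eps, sigma=cfg.sigma,
            silhouette_singleton_only=cfg.silhouette_singleton_only,
        )
    scores = membership_metrics.grade_segments(ztests, cluster, cfg, kept)
    result = evaluation.evaluate_grading(
        scores.activity[metric].to_numpy(),
        features.iloc[test_idx]["activity_pct"].to_numpy(),
        metric=metric,
        feature_subset=subset,
        threshold_pct=threshold_pct,
    )
    if use_abs and result.rho is not None:
        result.rho = result.abs_rho
    return result
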