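"""Synthetic bowel-sound datasets with exactly known activity percentages.

Real phonoenterogram corpora are not redistributable here, so the test bed
is generated: each "recording" is one fixed-length segment of low-level
background noise, and test segments additionally carry band-limited bursts
— exponentially damped narrow-band events whose energy sits inside the
100-1000 Hz analysis band, a crude but sufficient stand-in for the
rumbling/gurgling character of peristaltic sounds.  Bursts are placed
without overlap, so the annotated intervals account for the activity
percentage exactly.

The generator exercises the statistical structure the grading method relies
on (transient band-limited events over a stationary floor, with a clean
zero-activity pool); it makes no claim of physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, membership_metrics, pipeline
from .errors import InvalidArgumentError
from .signal_ingest import (
    ActivityAnnotation,
    AudioRecording,
    Segment,
    write_annotations,
    write_wav,
)

#: Tolerance (percentage points) on the per-segment activity target.
ACTIVITY_TOL_PCT = 2.0


@dataclass
class SynthConfig:
    """Study-condition parameters of the generated dataset.

    Defaults mirror the conditions the package is evaluated under: 2-s
    segments at 44.1 kHz, 50 zero-activity controls, 40 test segments
    spanning 10-80% activity, bursts 20 dB above a white noise floor of
    RMS 0.01, burst carriers 150-900 Hz lasting 30-150 ms.
    """

    sample_rate: int = 44100
    seg_len: float = 2.0
    n_control: int = 50
    n_test: int = 40
    activity_range: tuple[float, float] = (10.0, 80.0)
    burst_dur_ms: tuple[float, float] = (30.0, 150.0)
    burst_freq_hz: tuple[float, float] = (150.0, 900.0)
    burst_decay: float = 3.0            # envelope falls by e^-decay over the burst
    snr_db: float = 20.0
    noise_rms: float = 0.01
    noise_type: str = "white"           # "white" or "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_test < 0:
            raise InvalidArgumentError("segment counts must be non-negative")
        lo, hi = self.activity_range
        if not (0.0 < lo <= hi <= 100.0):
            raise InvalidArgumentError(f"activity_range must lie in (0, 100], got {self.activity_range}")
        if not (100.0 <= self.burst_freq_hz[0] <= self.burst_freq_hz[1] <= 1000.0):
            raise InvalidArgumentError("burst frequencies must lie within 100-1000 Hz")
        if not np.isfinite(self.snr_db):
            raise InvalidArgumentError("snr_db must be finite")
        if self.noise_type not in ("white", "pink"):
            raise InvalidArgumentError(f"unknown noise type {self.noise_type!r}")


@dataclass
class SynthDataset:
    """Generated recordings plus their annotations and ground truth."""

    recordings: list[AudioRecording]
    annotations: list[ActivityAnnotation]
    truth: pd.DataFrame                 # source_id, start_s, activity_pct
    config: SynthConfig = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> None:
        """Write WAV files, annotations.csv and truth.csv under out_dir."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in self.recordings:
            write_wav(out / f"{rec.source_id}.wav", rec)
        write_annotations(out / "annotations.csv", self.annotations)
        self.truth.to_csv(out / "truth.csv", index=False)


def _noise(n: int, rms: float, kind: str, rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    if kind == "pink":
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n)
        f[0] = f[1] if n > 1 else 1.0
        spec /= np.sqrt(f)
        x = np.fft.irfft(spec, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


def make_burst(
    duration_s: float,
    center_freq: float,
    sample_rate: int,
    rng: np.random.Generator,
    decay: float = 3.0,
) -> np.ndarray:
    """One damped narrow-band event, normalized to unit RMS.

    An exponentially decaying envelope multiplies a sinusoid at the given
    center frequency with random initial phase.
    """
    n = max(int(round(duration_s * sample_rate)), 2)
    t = np.arange(n) / sample_rate
    env = np.exp(-decay * t / duration_s)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    x = env * np.sin(2.0 * np.pi * center_freq * t + phase)
    return x / np.sqrt(np.mean(x**2))


def _draw_burst_intervals(
    target_pct: float, cfg: SynthConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Non-overlapping intervals whose total coverage hits the target."""
    target_dur = target_pct / 100.0 * cfg.seg_len
    if target_dur > cfg.seg_len:
        raise InvalidArgumentError(f"activity target {target_pct}% is infeasible")
    lo, hi = (d / 1000.0 for d in cfg.burst_dur_ms)
    durs: list[float] = []
    total = 0.0
    while total < target_dur - 1e-12:
        d = rng.uniform(lo, hi)
        if total + d > target_dur:
            d = target_dur - total      # trim the last burst to hit the target
        durs.append(d)
        total += d
    free = cfg.seg_len - total
    gaps = rng.dirichlet(np.ones(len(durs) + 1)) * free
    intervals = []
    cursor = 0.0
    for g, d in zip(gaps, durs):
        cursor += g
        intervals.append((cursor, cursor + d))
        cursor += d
    return intervals


def generate(config: SynthConfig) -> SynthDataset:
    """Generate controls (noise floor only) and annotated test segments.

    Burst amplitude is set so the burst RMS sits ``snr_db`` above the noise
    floor RMS.  The truth table is recomputed from the annotation intervals
    through :func:`evaluation.activity_percentage`, so it is consistent
    with what a round-trip through the annotation CSV would give.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.seg_len * cfg.sample_rate))
    burst_amp = 10.0 ** (cfg.snr_db / 20.0) * cfg.noise_rms

    recordings: list[AudioRecording] = []
    annotations: list[ActivityAnnotation] = []
    rows = []

    for i in range(cfg.n_control):
        sid = f"ctrl_{i:04d}"
        samples = _noise(n, cfg.noise_rms, cfg.noise_type, rng)
        recordings.append(AudioRecording(samples, cfg.sample_rate, sid))
        annotations.append(ActivityAnnotation(source_id=sid, intervals=[]))

    for i in range(cfg.n_test):
        sid = f"test_{i:04d}"
        target = rng.uniform(*cfg.activity_range)
        intervals = _draw_burst_intervals(target, cfg, rng)
        samples = _noise(n, cfg.noise_rms, cfg.noise_type, rng)
        for s, e in intervals:
            fc = rng.uniform(*cfg.burst_freq_hz)
            burst = make_burst(e - s, fc, cfg.sample_rate, rng, cfg.burst_decay)
            i0 = int(round(s * cfg.sample_rate))
            samples[i0 : i0 + burst.size] += burst_amp * burst[: n - i0]
        recordings.append(AudioRecording(samples, cfg.sample_rate, sid))
        annotations.append(ActivityAnnotation(source_id=sid, intervals=intervals))

    for rec, ann in zip(recordings, annotations):
        seg = Segment(rec.samples, rec.sample_rate, rec.source_id, 0.0, cfg.seg_len)
        rows.append({
            "source_id": rec.source_id,
            "start_s": 0.0,
            "activity_pct": evaluation.activity_percentage(seg, ann),
        })
    truth = pd.DataFrame(rows, columns=["source_id", "start_s", "activity_pct"])
    return SynthDataset(recordings, annotations, truth, cfg)


def end_to_end_fixture(
    config: SynthConfig,
    threshold_pct: float = 0.0,
    metric_config: membership_metrics.MetricConfig | None = None,
    feature_subset: tuple[str, ...] | None = None,
    metrics: tuple[str, ...] = membership_metrics.METRIC_NAMES,
) -> dict[str, evaluation.GradingEvaluation]:
    """Generate -> ingest -> extract -> grade -> evaluate, per metric."""
    dataset = generate(config)
    features = pipeline.extract_feature_table(dataset.recordings, dataset.annotations)
    return {
        m: pipeline.grade_and_evaluate(
            features, m, threshold_pct,
            feature_subset=feature_subset, config=metric_config,
        )
        for m in metrics
    }
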