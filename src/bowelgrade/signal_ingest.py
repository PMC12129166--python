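"""Audio ingestion: WAV reading, resampling, band-pass filtering, fixed-length
segmentation, and activity-annotation parsing.

Recordings are handled as float arrays normalized to [-1, 1].  The analysis
band is 100-1000 Hz, where bowel-sound (phonoenterogram) energy concentrates;
the band-pass is a 4th-order Butterworth applied forward-backward, so it is
zero-phase and annotated event positions survive filtering unchanged.
Time coordinates are 0-based seconds and intervals are half-open [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import butter, resample_poly, sosfiltfilt

from .errors import FormatError, InvalidArgumentError, InvalidInputError

logger = logging.getLogger(__name__)

#: Default analysis band (Hz).
DEFAULT_BAND = (100.0, 1000.0)
#: Default segment length in seconds.
DEFAULT_SEGMENT_LEN = 2.0


@dataclass
class AudioRecording:
    """A mono audio signal with amplitudes nominally in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise InvalidInputError("recording has no samples")
        if self.sample_rate <= 0:
            raise InvalidInputError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class Segment:
    """A fixed-duration excerpt of a recording, with provenance."""

    samples: np.ndarray
    sample_rate: int
    source_id: str
    start_time: float
    duration: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        expected = int(round(self.duration * self.sample_rate))
        if self.samples.size != expected:
            raise InvalidInputError(
                f"segment length {self.samples.size} != round(duration*rate) = {expected}"
            )


@dataclass
class ActivityAnnotation:
    """Interval labels (seconds) marking bowel-sound activity in one recording."""

    source_id: str
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def merged(self) -> list[tuple[float, float]]:
        """Union of the intervals as a sorted, non-overlapping list."""
        if not self.intervals:
            return []
        ivs = sorted(self.intervals)
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]


def read_wav(path: str | Path) -> AudioRecording:
    """Read a RIFF/WAVE file into a mono recording scaled to [-1, 1].

    Integer PCM is divided by full scale ``2**(bits-1)`` (scipy expands
    24-bit samples into the high bytes of int32, so int32 scaling covers
    both 24- and 32-bit PCM); float data is taken as-is.  Multichannel
    audio is averaged down to mono.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises assorted ValueError subclasses
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InvalidInputError(f"zero-length audio in {path}")
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype == np.int16:
        samples = data.astype(np.float64) / 2.0**15
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2.0**31
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecording(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as a float32 WAV file."""
    wavfile.write(str(path), rec.sample_rate, rec.samples.astype(np.float32))


def resample(rec: AudioRecording, target_rate: int) -> AudioRecording:
    """Polyphase (band-limited) resampling to ``target_rate`` Hz.

    Identity when the rates already match.  Output length is
    ``round(n * target_rate / rate)``.
    """
    if target_rate <= 0:
        raise InvalidArgumentError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.sample_rate:
        return AudioRecording(rec.samples.copy(), rec.sample_rate, rec.source_id)
    frac = Fraction(int(target_rate), int(rec.sample_rate))
    out = resample_poly(rec.samples, frac.numerator, frac.denominator)
    n_expected = int(round(rec.samples.size * target_rate / rec.sample_rate))
    if out.size > n_expected:
        out = out[:n_expected]
    elif out.size < n_expected:
        out = np.pad(out, (0, n_expected - out.size))
    return AudioRecording(out, int(target_rate), rec.source_id)


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    rec: AudioRecording, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]
) -> AudioRecording:
    """Zero-phase Butterworth band-pass (forward-backward, effective 8th order)."""
    nyq = rec.sample_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise InvalidArgumentError(
            f"cutoffs must satisfy 0 < low < high < fs/2; got {low}, {high} at fs={rec.sample_rate}"
        )
    sos = _bandpass_sos(low, high, rec.sample_rate)
    filtered = sosfiltfilt(sos, rec.samples)
    return AudioRecording(filtered, rec.sample_rate, rec.source_id)


def segment_fixed(rec: AudioRecording, seg_len: float = DEFAULT_SEGMENT_LEN) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping segments.

    A trailing remainder shorter than ``seg_len`` is dropped; a recording
    shorter than one segment yields an empty list.
    """
    if seg_len <= 0:
        raise InvalidArgumentError(f"seg_len must be positive, got {seg_len}")
    n_seg_samples = int(round(seg_len * rec.sample_rate))
    n_segments = rec.samples.size // n_seg_samples
    return [
        Segment(
            samples=rec.samples[i * n_seg_samples : (i + 1) * n_seg_samples],
            sample_rate=rec.sample_rate,
            source_id=rec.source_id,
            start_time=i * seg_len,
            duration=seg_len,
        )
        for i in range(n_segments)
    ]


def load_annotations(
    path: str | Path, durations: dict[str, float] | None = None
) -> list[ActivityAnnotation]:
    """Parse an annotation CSV (``source_id,start_s,end_s``, one interval/row).

    Intervals running past the known recording duration are clipped;
    intervals empty after clipping (or with end <= start) are discarded
    with a warning — hand-placed labels are tolerated, not rejected.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse annotation CSV {path}: {exc}") from exc
    required = {"source_id", "start_s", "end_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation CSV {path} missing columns: {sorted(missing)}")
    for col in ("start_s", "end_s"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"annotation column {col!r} is not numeric in {path}")

    out: dict[str, ActivityAnnotation] = {}
    for row in df.itertuples(index=False):
        sid = str(row.source_id)
        start = max(float(row.start_s), 0.0)
        end = float(row.end_s)
        if durations is not None and sid in durations:
            if end > durations[sid]:
                logger.warning(
                    "annotation for %s clipped: end %.3f s exceeds duration %.3f s",
                    sid, end, durations[sid],
                )
                end = durations[sid]
        if end <= start:
            logger.warning(
                "annotation for %s discarded: empty interval (%.3f, %.3f)", sid, start, end
            )
            continue
        out.setdefault(sid, ActivityAnnotation(source_id=sid)).intervals.append((start, end))
    return list(out.values())


def write_annotations(path: str | Path, annotations: list[ActivityAnnotation]) -> None:
    """Write annotations in the CSV schema that :func:`load_annotations` reads."""
    rows = [
        {"source_id": ann.source_id, "start_s": s, "end_s": e}
        for ann in annotations
        for s, e in ann.intervals
    ]
    pd.DataFrame(rows, columns=["source_id", "start_s", "end_s"]).to_csv(path, index=False)
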