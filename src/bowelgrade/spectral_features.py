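"""Windowed spectral features and their per-segment variability summary.

Each 2-s segment is cut into short Hamming-windowed frames (12.5 ms window,
6.25 ms hop by default), a one-sided magnitude spectrum is taken per frame,
and eleven spectral descriptors are computed per frame.  The segment
descriptor is the per-feature *standard deviation* across frames: bowel
sounds are transient, so a segment containing activity shows more
frame-to-frame spectral variability than background noise does.

All features operate on the magnitude spectrum (not power).  Degenerate
all-zero frames — possible after band-passing near-silence — yield a zero
feature row rather than NaNs, so they cannot poison the std aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError
from .signal_ingest import Segment

logger = logging.getLogger(__name__)

#: Canonical feature order; every downstream column index refers to this.
FEATURE_NAMES = (
    "centroid",
    "crest",
    "decrease",
    "entropy",
    "flatness",
    "kurtosis",
    "rolloff",
    "skewness",
    "slope",
    "spread",
    "harmonic_ratio",
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass
class FeatureConfig:
    """Windowing and feature parameters.

    win_len / hop are in seconds; rolloff_frac is the cumulative-magnitude
    fraction defining the roll-off point; the harmonic-ratio lag range
    defaults to the analysis band (100-1000 Hz).
    """

    win_len: float = 0.0125
    hop: float = 0.00625
    rolloff_frac: float = 0.95
    hr_min_freq: float = 100.0
    hr_max_freq: float = 1000.0


@dataclass
class FrameSpectrum:
    """One-sided magnitude spectrum of a single analysis frame."""

    magnitudes: np.ndarray
    bin_freqs: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=np.float64)
        if self.magnitudes.shape != self.bin_freqs.shape:
            raise InvalidInputError("magnitudes and bin_freqs differ in length")
        if np.any(self.magnitudes < 0) or not np.all(np.isfinite(self.magnitudes)):
            raise InvalidInputError("magnitudes must be finite and non-negative")
        if np.any(np.diff(self.bin_freqs) <= 0):
            raise InvalidInputError("bin_freqs must be strictly increasing")


@dataclass
class WindowedFeatureMatrix:
    """frames x 11 matrix of per-frame feature values."""

    values: np.ndarray
    frame_times: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES


@dataclass
class SegmentFeatureVector:
    """Per-feature sample standard deviation across a segment's frames."""

    values: np.ndarray
    source_id: str = ""
    start_time: float = 0.0
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)


def frame_segment(seg: Segment, win_len: float = 0.0125, hop: float = 0.00625) -> np.ndarray:
    """Slice a segment into Hamming-windowed frames.

    Returns an (n_frames, L) array with L = round(win_len*fs) and hop
    H = round(hop*fs); n_frames = floor((N-L)/H) + 1.
    """
    if not (win_len > hop > 0):
        raise InvalidArgumentError(f"need win_len > hop > 0, got {win_len}, {hop}")
    fs = seg.sample_rate
    L = int(round(win_len * fs))
    H = int(round(hop * fs))
    n = seg.samples.size
    if n < L:
        raise InvalidInputError(f"segment of {n} samples shorter than one window ({L})")
    n_frames = (n - L) // H + 1
    idx = np.arange(L)[None, :] + H * np.arange(n_frames)[:, None]
    return seg.samples[idx] * np.hamming(L)[None, :]


def _raw_frames(seg: Segment, win_len: float, hop: float) -> np.ndarray:
    """Un-windowed frames with the same geometry as :func:`frame_segment`."""
    fs = seg.sample_rate
    L = int(round(win_len * fs))
    H = int(round(hop * fs))
    n_frames = (seg.samples.size - L) // H + 1
    idx = np.arange(L)[None, :] + H * np.arange(n_frames)[:, None]
    return seg.samples[idx]


def frame_spectrum(frame: np.ndarray, sample_rate: float, frame_index: int = 0) -> FrameSpectrum:
    """One-sided magnitude spectrum of a (windowed) frame; bins k*fs/L."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise InvalidInputError("empty frame")
    mags = np.abs(np.fft.rfft(frame))
    freqs = np.fft.rfftfreq(frame.size, d=1.0 / sample_rate)
    return FrameSpectrum(magnitudes=mags, bin_freqs=freqs, frame_index=frame_index)


# ---------------------------------------------------------------------------
# Vectorized feature kernels.  S is (F, B) magnitudes, f is (B,) bin freqs.
# Degenerate rows (sum == 0) are zeroed by the caller; kernels may assume
# row sums > 0 unless noted.
# ---------------------------------------------------------------------------

def _moments_kernel(S: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, ...]:
    tot = S.sum(axis=1)
    centroid = (S * f).sum(axis=1) / tot
    dev = f[None, :] - centroid[:, None]
    var = (S * dev**2).sum(axis=1) / tot
    spread = np.sqrt(var)
    # sigma == 0 (point mass): skewness and kurtosis defined as 0
    safe = np.where(spread > 0, spread, 1.0)
    skewness = np.where(spread > 0, (S * dev**3).sum(axis=1) / (safe**3 * tot), 0.0)
    kurtosis = np.where(spread > 0, (S * dev**4).sum(axis=1) / (safe**4 * tot), 0.0)
    return centroid, spread, skewness, kurtosis


def _shape_kernel(
    S: np.ndarray, f: np.ndarray, rolloff_frac: float
) -> tuple[np.ndarray, ...]:
    F, B = S.shape
    tot = S.sum(axis=1)
    mean = tot / B
    crest = S.max(axis=1) / mean
    p = S / tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1) / np.log(B) if B > 1 else np.zeros(F)
    # flatness: geometric/arithmetic mean; any exactly-zero bin -> 0 (limit)
    has_zero = (S == 0).any(axis=1)
    logS = np.log(np.where(S > 0, S, 1.0))
    geo = np.exp(logS.mean(axis=1))
    flatness = np.where(has_zero, 0.0, geo / mean)
    # decrease: mean slope relative to the first bin, weighted 1/(k-1)
    k = np.arange(2, B + 1, dtype=np.float64)
    tail = S[:, 1:].sum(axis=1)
    num = ((S[:, 1:] - S[:, :1]) / (k - 1)).sum(axis=1)
    decrease = np.where(tail > 0, num / np.where(tail > 0, tail, 1.0), 0.0)
    # rolloff: lowest bin frequency reaching rolloff_frac of total magnitude
    cums = S.cumsum(axis=1)
    reach = cums >= (rolloff_frac * tot)[:, None] - 1e-15 * tot[:, None]
    rolloff = f[reach.argmax(axis=1)]
    # slope: least-squares line of magnitude vs frequency
    fdev = f - f.mean()
    slope = ((S - mean[:, None]) * fdev).sum(axis=1) / (fdev**2).sum()
    return crest, decrease, entropy, flatness, rolloff, slope


def spectral_moments(sp: FrameSpectrum) -> tuple[float, float, float, float]:
    """(centroid Hz, spread Hz, skewness, kurtosis) of a magnitude spectrum.

    The spectrum is treated as a mass distribution over bin frequencies;
    a point-mass spectrum (spread 0) returns skewness = kurtosis = 0.
    """
    S = sp.magnitudes[None, :]
    if S.sum() <= 0:
        raise InvalidInputError("all-zero spectrum has no moments")
    c, sp_, sk, ku = _moments_kernel(S, sp.bin_freqs)
    return float(c[0]), float(sp_[0]), float(sk[0]), float(ku[0])


def spectral_shape(
    sp: FrameSpectrum, rolloff_frac: float = 0.95
) -> tuple[float, float, float, float, float, float]:
    """(crest, decrease, entropy, flatness, rolloff Hz, slope)."""
    if not (0.0 < rolloff_frac < 1.0):
        raise InvalidArgumentError(f"rolloff_frac must be in (0,1), got {rolloff_frac}")
    S = sp.magnitudes[None, :]
    if S.sum() <= 0:
        raise InvalidInputError("all-zero spectrum has no shape features")
    cr, de, en, fl, ro, sl = _shape_kernel(S, sp.bin_freqs, rolloff_frac)
    return float(cr[0]), float(de[0]), float(en[0]), float(fl[0]), float(ro[0]), float(sl[0])


def _harmonic_ratio_kernel(
    frames: np.ndarray, fs: float, min_lag_freq: float, max_lag_freq: float
) -> np.ndarray:
    """Max normalized autocorrelation over lags in [fs/max_f, fs/min_f]."""
    F, L = frames.shape
    lag_min = max(int(round(fs / max_lag_freq)), 1)
    lag_max = int(round(fs / min_lag_freq))
    if lag_max >= L:
        raise InvalidArgumentError(
            f"frame of {L} samples cannot hold one period of {min_lag_freq} Hz at fs={fs}"
        )
    nfft = int(2 ** np.ceil(np.log2(2 * L)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : lag_max + 1]
    sq = np.concatenate([np.zeros((F, 1)), np.cumsum(frames**2, axis=1)], axis=1)
    lags = np.arange(lag_min, lag_max + 1)
    # energy of x[:L-tau] and x[tau:] for each lag
    e_head = sq[:, L - lags]                  # (F, n_lags)
    e_tail = sq[:, [L]] - sq[:, lags]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, acf[:, lag_min:] / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r.max(axis=1, initial=0.0), 0.0, 1.0)


def harmonic_ratio(
    frame: np.ndarray,
    fs: float,
    min_lag_freq: float = 100.0,
    max_lag_freq: float = 1000.0,
) -> float:
    """Peak normalized autocorrelation of an un-windowed frame, in [0, 1].

    The lag search covers periods of ``max_lag_freq`` down to
    ``min_lag_freq``; periodic (tonal) frames score near 1, noise-like
    frames low.
    """
    frame = np.asarray(frame, dtype=np.float64)
    return float(_harmonic_ratio_kernel(frame[None, :], fs, min_lag_freq, max_lag_freq)[0])


def extract_windowed(seg: Segment, config: FeatureConfig | None = None) -> WindowedFeatureMatrix:
    """Frame a segment and compute the 11 features for every frame."""
    cfg = config or FeatureConfig()
    windowed = frame_segment(seg, cfg.win_len, cfg.hop)
    raw = _raw_frames(seg, cfg.win_len, cfg.hop)
    F, L = windowed.shape
    S = np.abs(np.fft.rfft(windowed, axis=1))
    f = np.fft.rfftfreq(L, d=1.0 / seg.sample_rate)

    tot = S.sum(axis=1)
    live = tot > 0
    n_dead = int((~live).sum())
    if n_dead:
        logger.warning(
            "%d of %d frames in segment %s@%.1fs are all-zero; features set to 0",
            n_dead, F, seg.source_id, seg.start_time,
        )

    out = np.zeros((F, N_FEATURES))
    if live.any():
        Sl = S[live]
        centroid, spread, skew, kurt = _moments_kernel(Sl, f)
        crest, decrease, entropy, flatness, rolloff, slope = _shape_kernel(
            Sl, f, cfg.rolloff_frac
        )
        cols = {
            "centroid": centroid, "crest": crest, "decrease": decrease,
            "entropy": entropy, "flatness": flatness, "kurtosis": kurt,
            "rolloff": rolloff, "skewness": skew, "slope": slope, "spread": spread,
        }
        for name, vals in cols.items():
            out[live, FEATURE_NAMES.index(name)] = vals
    hr = _harmonic_ratio_kernel(raw, seg.sample_rate, cfg.hr_min_freq, cfg.hr_max_freq)
    out[:, FEATURE_NAMES.index("harmonic_ratio")] = np.where(live, hr, 0.0)

    H = int(round(cfg.hop * seg.sample_rate))
    frame_times = seg.start_time + np.arange(F) * H / seg.sample_rate
    return WindowedFeatureMatrix(values=out, frame_times=frame_times)


def summarize_segment(m: WindowedFeatureMatrix) -> np.ndarray:
    """Per-feature sample (n-1) standard deviation across frames."""
    if m.values.shape[0] < 2:
        raise InvalidInputError("need at least 2 frames to compute a standard deviation")
    return m.values.std(axis=0, ddof=1)


def extract_segment_vector(seg: Segment, config: FeatureConfig | None = None) -> SegmentFeatureVector:
    """Full per-segment pipeline: windowed features -> std vector."""
    m = extract_windowed(seg, config)
    return SegmentFeatureVector(
        values=summarize_segment(m), source_id=seg.source_id, start_time=seg.start_time
    )
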