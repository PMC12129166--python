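import numpy as np
import pandas as pd
import pytest

from bowelgrade.membership_metrics import ControlCluster
from bowelgrade.signal_ingest import AudioRecording, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """2-s unit-amplitude 500 Hz sine at 44.1 kHz (mid-band tone)."""
    fs = 44100
    t = np.arange(2 * fs) / fs
    return AudioRecording(np.sin(2 * np.pi * 500 * t), fs, "sine500")


@pytest.fixture
def noise_segment(rng):
    """2-s white-noise segment at 8 kHz (cheap stand-in for background)."""
    fs = 8000
    return Segment(rng.standard_normal(2 * fs) * 0.01, fs, "noise", 0.0, 2.0)


@pytest.fixture
def small_cluster():
    """1-D control members at 0 and 2 (the hand-worked fixture)."""
    return ControlCluster(np.array([[0.0], [2.0]]))


def make_ranking_table(rng, n_control=30, n_test=25, p=4, informative=("slope",)):
    """A cheap feature table (no audio) whose informative columns track
    activity_pct; the rest are noise.  Used by selection/evaluation tests."""
    from bowelgrade.spectral_features import FEATURE_NAMES

    names = FEATURE_NAMES[:p]
    act = np.concatenate([np.zeros(n_control), rng.uniform(5, 95, n_test)])
    rows = []
    for i, a in enumerate(act):
        row = {"source_id": f"s{i:03d}", "start_s": 0.0, "activity_pct": a}
        for name in names:
            if name in informative:
                row[name] = a / 50.0 + rng.normal(0, 0.15)
            else:
                row[name] = rng.normal(0, 1)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def ranking_table(rng):
    from bowelgrade.spectral_features import FEATURE_NAMES

    return make_ranking_table(rng, p=4, informative=(FEATURE_NAMES[3],))
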