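import numpy as np
import pytest

from bfndecode import io as bio


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_eeg(n_channels=3, n_times=1000, rate=1000.0, rng=None, labels=None, start=0.0):
    rng = rng or np.random.default_rng(0)
    labels = labels or ["C3", "CZ", "C4", "F3", "F4", "P3", "P4", "O1"][:n_channels]
    return bio.EEGRecording(
        samples=rng.standard_normal((n_channels, n_times)),
        rate=rate,
        channel_labels=labels,
        start_time=start,
    )


def make_trajectory(duration=10.0, rate=120.0, start=0.0, fn=None, inclusive=False):
    n = int(round(duration * rate)) + (1 if inclusive else 0)
    t = start + np.arange(n) / rate
    if fn is None:
        fn = lambda t: (np.sin(t), np.cos(t), t * 0.1)
    x, y, z = fn(t)
    return bio.TrajectoryRecording(
        times=t, x=np.broadcast_to(x, t.shape).copy(),
        y=np.broadcast_to(y, t.shape).copy(),
        z=np.broadcast_to(z, t.shape).copy(), rate=rate,
    )


@pytest.fixture
def small_trial():
    """A 10-s synced + epoched trial with 4 channels at 200 Hz."""
    rng = np.random.default_rng(7)
    eeg = make_eeg(4, 2000, rate=200.0, rng=rng, labels=["C3", "CZ", "C4", "CP4"])
    traj = make_trajectory(duration=10.0)
    trial = bio.synchronize(eeg, traj, analysis_rate=50.0, mode="UD")
    return bio.epoch(trial, 2.0)
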