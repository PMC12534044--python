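import numpy as np
import pytest

from pawkit.stimulus import sine_poke_profile
from pawkit.synth import WithdrawalParams, synth_withdrawal_track
from pawkit.track_io import PoseTrack, compute_calibration


@pytest.fixture(scope="session")
def pinprick():
    """Standard pinprick delivery profile (A=8 mm, λ=0.8 s, mesh 14 mm)."""
    return sine_poke_profile()


@pytest.fixture(scope="session")
def clean_trial(pinprick):
    """One noiseless, dropout-free synthetic withdrawal with ground truth."""
    params = WithdrawalParams(seed=7, noise_sd_mm=0.0, dropout_prob=0.0)
    track, truth = synth_withdrawal_track(params, pinprick)
    return params, track, truth


@pytest.fixture(scope="session")
def noisy_trial(pinprick):
    """A realistic trial: tracking noise and dropout at generator defaults."""
    params = WithdrawalParams(seed=11)
    track, truth = synth_withdrawal_track(params, pinprick)
    return params, track, truth


def make_simple_track(y, fps=2000.0, units="mm", x=None, conf=None, t0=0.0):
    """Single-paw track (heel/center/toe share the series) for unit tests."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.zeros(n) if x is None else np.asarray(x, dtype=float)
    conf = np.ones(n) if conf is None else np.asarray(conf, dtype=float)
    coords = np.zeros((3, n, 2))
    confidence = np.zeros((3, n))
    for i in range(3):
        coords[i, :, 0] = x
        coords[i, :, 1] = y
        confidence[i] = conf
    return PoseTrack(["heel", "center", "toe"], coords, confidence,
                     fps=fps, units=units, meta={"t0_s": t0})


@pytest.fixture(scope="session")
def calibrated(noisy_trial):
    params, track, truth = noisy_trial
    return compute_calibration(track, params.known_mm)
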