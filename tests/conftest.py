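import numpy as np
import pandas as pd
import pytest

from gazescaffold import AnalysisConfig, GazeRecording
from gazescaffold.preprocess import EpochSet


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def flat_recording():
    """20 s of quiet fixation with a pupil channel and no blinks."""
    n = 20_000
    t = np.arange(n, dtype=float)
    return GazeRecording(time=t, x=np.zeros(n), y=np.zeros(n),
                        valid=np.ones(n, bool), pupil=np.full(n, 1000.0))


def make_recording(x, y, pupil=None, valid=None):
    n = len(x)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    return GazeRecording(time=np.arange(n, dtype=float), x=x, y=y,
                         valid=valid, pupil=pupil)


def make_epochs(x, y, trials=None, time=None, baseline_applied=True,
                included=None):
    """EpochSet straight from matrices, default time 0..n-1 ms."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n_tr, n_t = x.shape
    if time is None:
        time = np.arange(n_t, dtype=float)
    if trials is None:
        trials = pd.DataFrame({
            "trial_id": np.arange(n_tr),
            "cue_onset_ms": np.zeros(n_tr),
            "cued_direction": ["right"] * n_tr,
            "cued_distance": ["near"] * n_tr,
            "scaffold": ["direction_insufficient"] * n_tr,
            "config_axis": ["horizontal"] * n_tr,
            "correct": [True] * n_tr,
        })
    if included is None:
        included = np.ones(n_tr, bool)
    return EpochSet(time=np.asarray(time, float), x=x, y=y, trials=trials,
                    included=included, baseline_applied=baseline_applied)
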