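"""Shared fixtures: small synthetic subjects reused across test modules."""

import numpy as np
import pytest

from ckcpipe import SubjectSimConfig, generate_subject
from ckcpipe.preprocess import preprocess_recording


@pytest.fixture(scope="session")
def small_subject():
    """One 30 s single-trial subject with clear coupling, 16 channels."""
    cfg = SubjectSimConfig(duration=30, n_trials=1, n_channels=16, seed=42,
                           coupling_gain_f0=0.3, coupling_gain_f1=0.3)
    return generate_subject(cfg)


@pytest.fixture(scope="session")
def small_recording(small_subject):
    return small_subject.trials[0]


@pytest.fixture(scope="session")
def preprocessed_recording(small_recording):
    return preprocess_recording(small_recording).recording


@pytest.fixture(scope="session")
def burst_train():
    """Rectified synthetic burst train: 1.2 Hz Gaussian bursts, 60 s."""
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    env = np.zeros_like(t)
    for c in np.arange(0.4, 60, 1 / 1.2):
        env += np.exp(-0.5 * ((t - c) / 0.07) ** 2)
    return 0.1 + env, fs
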