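"""Shared fixtures: small, fast synthetic configurations.

Durations here are deliberately short (tens of seconds of wake EEG,
90-minute nights); statistical tolerances in the tests are set for
these sizes.
"""
import numpy as np
import pytest

from ctbseeg import Recording, SimConfig
from ctbseeg.io import WAKE_CHANNELS_21


@pytest.fixture(scope="session")
def clean_cfg():
    """No artifacts, no line noise, no coupling, no subject variability."""
    return SimConfig(n_subjects=2, wake_duration=60.0, artifact_rate=0.0,
                     line_noise_amplitude=0.0, coupling_pairs=(),
                     subject_effect_sd=0.0, baseline_power_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_cfg():
    """Defaults-like config with artifacts and line noise, short duration."""
    return SimConfig(n_subjects=2, wake_duration=120.0, artifact_rate=3.0,
                     line_noise_amplitude=5.0, coupling_pairs=(), seed=2)


@pytest.fixture(scope="session")
def sleep_cfg():
    """Short synthetic night covering at least the first sleep cycle."""
    return SimConfig(n_subjects=1, sleep_duration_minutes=90.0,
                     artifact_rate=0.5, line_noise_amplitude=5.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def make_recording(data, sfreq=1000.0, names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if names is None:
        names = list(WAKE_CHANNELS_21[: data.shape[0]])
    return Recording(data, names, sfreq)
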