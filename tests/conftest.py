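import numpy as np
import pytest

from flysteer import synthetic_data as sd
from flysteer.stimulus import ConditionKind, RotationDir, StimulusCondition

FS = 60.0


@pytest.fixture(scope="session")
def full_field_cw() -> StimulusCondition:
    return StimulusCondition(kind=ConditionKind.FULL_FIELD, rotation_dir=RotationDir.CW)


@pytest.fixture(scope="session")
def walker_session(full_field_cw):
    """A small deterministic walking session shared across tests."""
    params = sd.WalkerParams(seed=42)
    traj, gt, log = sd.simulate_walker(params, full_field_cw, n_trials=6)
    return params, traj, gt, log


@pytest.fixture(scope="session")
def detector_benchmark():
    """Ten planted-saccade benchmark trials (smooth bg + raised-cosine pulses)."""
    return sd.make_detector_benchmark(10, seed=123)


def planted_pulse(n=600, fs=FS, t0=5.0, duration=0.12, peak=500.0):
    return sd.raised_cosine_pulse(n, fs, t0, duration, peak)
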