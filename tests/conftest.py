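import numpy as np
import pytest

from drivestress.cli import analyze_session
from drivestress.io_signals import StudyConfig, SubjectMeta
from drivestress.synth import GeneratorParams, generate_session


@pytest.fixture(scope="session")
def elderly_session():
    """One default synthetic elderly session (ECG, accel, truth, params)."""
    params = GeneratorParams(group="elderly", seed=11)
    ecg, accel, truth, _ = generate_session(params)
    return ecg, accel, truth, params


@pytest.fixture(scope="session")
def elderly_report(elderly_session):
    """Full-pipeline report for the default elderly session (tachy flagging)."""
    ecg, accel, truth, params = elderly_session
    config = StudyConfig(seed=11, direction="below")
    subject = SubjectMeta(subject_id="e11", age=65, group="elderly")
    return analyze_session(ecg, accel, subject, params.stages, config)


def beat_train(rate_bpm: float = 60.0, duration_s: float = 120.0, start_s: float = 0.5):
    """Evenly spaced beat times for detector tests."""
    rr = 60.0 / rate_bpm
    return np.arange(start_s, duration_s - 0.3, rr)
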