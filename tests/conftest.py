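import numpy as np
import pytest

from vogcover import (
    SubjectSimParams,
    default_schedule,
    simulate_model_eye_session,
    simulate_subject_session,
)


@pytest.fixture(scope="session")
def protocol_schedule():
    """The clinical protocol: 10 s binocular lead + 5 x (5 s L / 5 s R)."""
    return default_schedule(n_cycles=5, binocular_lead_s=10.0, cover_s=5.0)


@pytest.fixture(scope="session")
def noiseless_session(protocol_schedule):
    """15 deg exotropia, no noise of any kind."""
    params = SubjectSimParams(true_deviation_deg=15.0, phoria_noise_sd_deg=0.0,
                              trace_noise_sd_deg=0.0, blink_rate_hz=0.0, seed=7)
    return simulate_subject_session(params, protocol_schedule)


@pytest.fixture(scope="session")
def model_eye_session():
    """Noiseless 16-dwell calibration session with the affine device
    distortion injected; low frame rate keeps the stack small (the dwell
    positions are static so the rate does not affect dwell medians)."""
    return simulate_model_eye_session(device_slope=0.978,
                                      device_intercept=-0.549,
                                      frame_rate_hz=4.0, seed=3)
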