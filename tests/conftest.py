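import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crtpipe import PipelineConfig
from crtpipe.simulate import SimulationParams, simulate_session

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_session():
    """Small noise-free session (5 cycles): the simplest full recording."""
    params = SimulationParams(
        session_length_s=23.0 * 5,
        noise_sd_counts=0.0,
        cardiac_amplitude_counts=0.0,
        temp_noise_sd_c=0.0,
        seed=1,
    )
    return simulate_session(params)


@pytest.fixture(scope="session")
def noisy_session():
    """Default study conditions (1% noise, cardiac ripple), 40 cycles."""
    params = SimulationParams(session_length_s=23.0 * 40, seed=2)
    return simulate_session(params)


@pytest.fixture(scope="session")
def cooling_session():
    """One subject cooled by 8 degC over ~78 min, -5%/degC CRT sensitivity."""
    length = 23.0 * 205
    params = SimulationParams(
        session_length_s=length,
        seed=3,
        temp_sensitivity_per_c=-0.05,
        temperature_profile=((0.0, length), (33.0, 25.0)),
    )
    return simulate_session(params)


@pytest.fixture(scope="session")
def cooling_refills(cooling_session):
    from crtpipe.refill import analyze_recording

    rec, truth = cooling_session
    return analyze_recording(rec, PipelineConfig(), wavelengths=[520])
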