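import pytest

from hergpower import (
    APShapeParams,
    build_ap_waveform,
    default_wt_model,
    scale_for_temperature,
    simulate_current,
)


@pytest.fixture(scope="session")
def protocol():
    """Standard AP-clamp command at the default 0.5 ms sampling."""
    return build_ap_waveform(APShapeParams())


@pytest.fixture(scope="session")
def coarse_protocol():
    """1 ms-sampled AP command for ODE-heavy multi-simulation tests."""
    return build_ap_waveform(APShapeParams(sample_interval=1.0))


@pytest.fixture(scope="session")
def wt_model():
    return default_wt_model()


@pytest.fixture(scope="session")
def wt37_trace(wt_model, protocol):
    """Reference wild-type simulation at 37°C (shared, read-only)."""
    return simulate_current(scale_for_temperature(wt_model, 37.0), protocol)
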