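import numpy as np
import pytest

from mwlkit import (
    EEGGenConfig,
    GazeGenConfig,
    SessionConfig,
    UAVGenConfig,
    ClickGenConfig,
    make_phase_schedule,
    generate_workload_profile,
)


@pytest.fixture(scope="session")
def default_schedule():
    return make_phase_schedule()


@pytest.fixture(scope="session")
def fast_config():
    """A short session (4 min) at reduced rates, for quick pipeline tests."""
    schedule = make_phase_schedule((30.0, 60.0, 60.0, 60.0, 30.0))
    return SessionConfig(
        schedule=schedule,
        eeg=EEGGenConfig(fs=64.0),
        gaze=GazeGenConfig(fs=30.0),
        uav=UAVGenConfig(counts=(0, 2, 4, 6, 6), base_event_rate_per_min=0.2,
                         event_rate_gain_per_min=2.0, repair_mean_s=20.0),
        clicks=ClickGenConfig(base_rate_hz=0.3, rate_gain_hz=1.5),
    )


@pytest.fixture(scope="session")
def fast_analysis_config():
    """Analysis parameters scaled to the short fixture's 30-60 s phases."""
    from mwlkit import AnalysisConfig

    return AnalysisConfig(entropy_window_s=20.0, min_transitions=3, click_bin_s=30.0)


@pytest.fixture(scope="session")
def fast_profile(fast_config):
    return generate_workload_profile(fast_config.schedule, fast_config.levels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
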