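import numpy as np
import pytest

from pawtrigger import (
    CriterionConfig,
    MotionScript,
    ReachEvent,
    SessionConfig,
    generate_pose_trace,
)


@pytest.fixture(scope="session")
def short_session_config() -> SessionConfig:
    """Scaled trial timing for fast tests: 2 s buffer + 18 s recording."""
    return SessionConfig(buffer_duration=2.0, recording_duration=18.0)


@pytest.fixture(scope="session")
def clean_script() -> MotionScript:
    """Deterministic 20 s session: three spaced left reaches, no noise/drops."""
    return MotionScript(
        duration=20.0,
        frame_rate=100.0,
        reach_events=(
            ReachEvent(4.0, "left", 40.0, 0.1),
            ReachEvent(9.0, "left", 40.0, 0.1),
            ReachEvent(14.0, "left", 40.0, 0.1),
        ),
        baseline_jitter_sd=0.0,
        drop_probability=0.0,
        timestamp_jitter_sd=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_session(clean_script):
    return generate_pose_trace(clean_script)


@pytest.fixture
def default_criterion() -> CriterionConfig:
    return CriterionConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
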