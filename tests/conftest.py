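import numpy as np
import pytest

from vitalmvpa import (
    GeometryConfig,
    NoiseConfig,
    SignalConfig,
    build_geometry,
    build_pattern_set,
    generate_session_design,
    simulate_run,
)


@pytest.fixture(scope="session")
def reduced_geometry():
    return GeometryConfig().scaled(0.1)


@pytest.fixture(scope="session")
def reduced_rois(reduced_geometry):
    return build_geometry(reduced_geometry, SignalConfig(), seed=3)


@pytest.fixture(scope="session")
def session_design():
    return generate_session_design("sub-00", seed=11)


@pytest.fixture(scope="session")
def noisy_subject(reduced_rois, session_design):
    """One reduced-resolution subject at the default signal/noise settings."""
    runs = [
        simulate_run(d, reduced_rois, SignalConfig(), NoiseConfig(), seed=500 + i)
        for i, d in enumerate(session_design.runs)
    ]
    patterns = {
        roi: build_pattern_set(runs, session_design.runs, reduced_rois, roi, "sub-00")
        for roi in ("left_insula", "ctrl_white_matter")
    }
    return {"runs": runs, "patterns": patterns, "rois": reduced_rois}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
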