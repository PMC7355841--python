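import numpy as np
import pytest

from gazerr.pipeline import sessions_to_error_traces
from gazerr.simulate import SimulationSpec, default_profiles, simulate_study


@pytest.fixture(scope="session")
def desktop_traces():
    """Cleaned error traces of a full simulated 20-participant desktop study."""
    spec = SimulationSpec(platform="desktop", participants=20, seed=7)
    sessions = simulate_study(spec, default_profiles("desktop"))
    return sessions_to_error_traces(sessions)


@pytest.fixture(scope="session")
def tablet_traces():
    spec = SimulationSpec(platform="tablet", participants=20, seed=11)
    sessions = simulate_study(spec, default_profiles("tablet"))
    return sessions_to_error_traces(sessions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
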