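import numpy as np
import pytest

from yubadry.twin import TwinParams, default_scenarios, simulate


@pytest.fixture(scope="session")
def params() -> TwinParams:
    return TwinParams()


@pytest.fixture(scope="session")
def traj60(params):
    """Noise-free constant-60-degC run to the moisture endpoint."""
    return simulate(60.0, params)


@pytest.fixture(scope="session")
def scenario_trajectories(params):
    """Noise-free runs of the full scenario set (5 constant + 2 varying)."""
    return [simulate(profile, params) for profile in default_scenarios()]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
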