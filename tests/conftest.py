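import numpy as np
import pytest

from affectemg.preprocess import preprocess_recording
from affectemg.synthetic import SimulationConfig, make_schedule, simulate_recording


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def schedule():
    return make_schedule(seed=0)


@pytest.fixture(scope="session")
def recording(schedule, default_config):
    rec, labels = simulate_recording(schedule, default_config)
    return rec, labels


@pytest.fixture(scope="session")
def clean_recording(schedule, default_config):
    rec, _ = simulate_recording(schedule, default_config)
    return preprocess_recording(rec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
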