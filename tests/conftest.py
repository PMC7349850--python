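import numpy as np
import pytest

from eegconnectome.montage import synthetic_montage
from eegconnectome.simulate import SimulationConfig, generate_cohort

TINY_GROUPS = {"HC": 3, "SCD": 3, "MCI": 3, "AD": 3}


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small four-group cohort: 16 channels, 20 s, one bad channel."""
    return SimulationConfig(
        group_sizes=dict(TINY_GROUPS),
        n_channels=16,
        duration_s=20.0,
        bad_channel_count=1,
        artifact_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def montage16():
    return synthetic_montage(16)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
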