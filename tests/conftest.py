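import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epimsap import MSAPMatrix, SimConfig, TypeCounts

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def control_counts() -> TypeCounts:
    """Band-type counts of the untreated (0 mM) profile: 246 loci."""
    return TypeCounts(110, 11, 73, 52)


@pytest.fixture
def small_matrix() -> MSAPMatrix:
    """4 individuals x 3 loci with one missing cell; codes 1..4 = types I..IV."""
    calls = np.array(
        [
            [1, 2, 1],
            [1, 3, 1],
            [1, 4, -1],
            [1, 1, 1],
        ],
        dtype=np.int8,
    )
    return MSAPMatrix(
        individuals=["i1", "i2", "i3", "i4"],
        groups=["ctrl", "ctrl", "azaC", "azaC"],
        loci=["L1", "L2", "L3"],
        calls=calls,
    )


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(seed=20160936)
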