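import sys
from pathlib import Path

import pytest
from hypothesis import settings as hypothesis_settings

sys.path.insert(0, str(Path(__file__).parent))

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

from photoalloc import (
    Allocation,
    EnergyPartition,
    Environment,
    OptimizerSettings,
    StoichiometryConstants,
    default_environments,
    default_species,
)


@pytest.fixture(scope="session")
def constants():
    return StoichiometryConstants()


@pytest.fixture(scope="session")
def species():
    return default_species()


@pytest.fixture(scope="session")
def environments():
    return default_environments()


@pytest.fixture(scope="session")
def evo_env(environments):
    return environments["evolutionary"]


@pytest.fixture(scope="session")
def c3(species):
    return species["C3"]


@pytest.fixture(scope="session")
def c4(species):
    return species["C4"]


@pytest.fixture
def c4_alloc():
    return Allocation(n_Etot=0.25, n_C4=0.08, n_Jmax=0.67, p=0.6)


@pytest.fixture
def c3_alloc():
    return Allocation(n_Etot=0.4, n_C4=0.0, n_Jmax=0.6, p=0.9)


@pytest.fixture
def c4_partition():
    return EnergyPartition(0.0, 0.5, 0.0, 0.1, 0.4)


@pytest.fixture
def c3_partition():
    return EnergyPartition(0.7, 0.0, 0.3, 0.0, 0.0)


@pytest.fixture
def quick_settings():
    return OptimizerSettings(n_starts=6, seed=11)


@pytest.fixture
def simple_env():
    return Environment(I=1000.0, T=25.0, C_m=150.0, O=200.0, N_t=100.0)
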