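import pytest
from hypothesis import HealthCheck, settings

from hemiphase import PhaseParams, datasets, phase_family

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return datasets.table1_registry()


@pytest.fixture(scope="session")
def table2():
    return datasets.table2_dataset()


@pytest.fixture(scope="session")
def table2_phased(table2):
    return [phase_family(f, table2.table, table2.registry, PhaseParams())
            for f in table2.families]
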