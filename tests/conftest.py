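import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mabflow import FunnelConfig, LineageStore, default_registry, default_schema, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture()
def store(schema):
    s = LineageStore(schema)
    yield s
    s.close()


@pytest.fixture(scope="session")
def small_cohort(registry):
    """A 96-cell cohort reused by read-only tests."""
    return generate_cohort(FunnelConfig(n_cells=96, seed=11), registry)
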