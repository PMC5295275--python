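import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ejdose",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ejdose")

from ejdose import RPFSet, default_inhalation_table
from ejdose.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def ef_table():
    return default_inhalation_table()


@pytest.fixture(scope="session")
def benzene_rpfs():
    return RPFSet(
        index_chemical="benzene",
        rpf={"benzene": 1.0, "butadiene": 6.0, "acetaldehyde": 0.44},
    )


@pytest.fixture(scope="session")
def small_records():
    """Fifty synthetic tracts with mild positive effects; shared read-only."""
    config = GeneratorConfig(n_tracts=50, seed=7)
    return generate(config)
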