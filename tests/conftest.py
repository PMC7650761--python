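import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """One seeded synthetic bundle shared across tests."""
    from termite_virome import synthetic_data as sd

    return sd.simulate_virome(sd.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    from termite_virome import pipeline

    return pipeline.run_on_bundle(bundle)
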