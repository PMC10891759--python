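import pytest
from hypothesis import HealthCheck, settings

from nadolol_pbpk import engine
from nadolol_pbpk.drug import nadolol_parameters
from nadolol_pbpk.physiology import reference_adult

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def ref_adult():
    return reference_adult()


@pytest.fixture(scope="session")
def nadolol():
    return nadolol_parameters()


@pytest.fixture(scope="session")
def adult_model(ref_adult, nadolol):
    return engine.build_model(ref_adult, nadolol)
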