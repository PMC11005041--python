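import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from toxscope import standardize_smiles  # noqa: E402


@pytest.fixture(scope="session")
def toluene():
    return standardize_smiles("Cc1ccccc1")


@pytest.fixture(scope="session")
def benzene():
    return standardize_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def parathion():
    return standardize_smiles("CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]")
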