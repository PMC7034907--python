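import pytest

from natronid import AttenuationTable, default_registry


@pytest.fixture(scope="session")
def table():
    return AttenuationTable.default()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def candidates(registry):
    return registry.natron_candidates()


# Printed reference values from the crocodile-mummy case study: the natron
# candidate table at the calibrated effective energy of 146.1 keV (cm^-1).
PRINTED_MU_146 = {
    "sodium_carbonate": (0.345, 0.21),
    "nahcolite": 0.3050,
    "halite": 0.3130,
    "sodium_sulphate": (0.373, 0.215),
    "trona": 0.298,
}


@pytest.fixture(scope="session")
def printed_mu():
    return PRINTED_MU_146
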