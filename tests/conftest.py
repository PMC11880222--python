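import pytest

from pbpkt.fixtures import (
    cf_config,
    dcm_config,
    fixture_chemical,
    fixture_physiology,
)


@pytest.fixture(scope="session")
def phys():
    return fixture_physiology()


@pytest.fixture(scope="session")
def chem_dcm():
    return fixture_chemical("dcm")


@pytest.fixture(scope="session")
def chem_cf():
    return fixture_chemical("cf")


@pytest.fixture(scope="session")
def chem_full():
    return fixture_chemical("full")


@pytest.fixture()
def cfg_dcm():
    return dcm_config()


@pytest.fixture()
def cfg_cf():
    return cf_config()
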