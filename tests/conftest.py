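import pytest

from neuropk import calibrate_bbb, get_biomarker, get_preset


@pytest.fixture(scope="session")
def calibration():
    """Adult-default barrier calibration, computed once per session."""
    return calibrate_bbb()


@pytest.fixture(scope="session")
def s100b():
    return get_biomarker("s100b_monomer")


@pytest.fixture(scope="session")
def adult_male():
    return get_preset("adult_male")


@pytest.fixture(scope="session")
def neonate():
    return get_preset("neonate")
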