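import pytest

from gisivivc import gis, synthetic


@pytest.fixture(scope="session")
def br_records():
    """Packaged pH-solubility measurements in Britton-Robinson buffers."""
    return synthetic.solubility_records("br_solubility")


@pytest.fixture(scope="session")
def bio_records():
    """Packaged biorelevant-media solubility measurements."""
    return synthetic.solubility_records("biorelevant_solubility")


@pytest.fixture(scope="session")
def uir():
    """Reference biexponential unit impulse response (400 mg)."""
    return synthetic.REFERENCE_UIR


@pytest.fixture(scope="session")
def gis_config():
    return gis.GISConfig()


@pytest.fixture(scope="session")
def solub_map(gis_config):
    return synthetic.solubility_map(gis_config)


@pytest.fixture(scope="session")
def scenarios():
    return gis.default_scenarios(dose=200.0)
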