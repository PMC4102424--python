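import pytest

from imsatkit.repeat_detection import ThresholdConfig
from imsatkit.synthetic_data import default_reporter_template


@pytest.fixture(scope="session")
def primate_cfg() -> ThresholdConfig:
    return ThresholdConfig.preset("primate")


@pytest.fixture(scope="session")
def population_cfg() -> ThresholdConfig:
    return ThresholdConfig.preset("population")


@pytest.fixture(scope="session")
def gt10_template():
    return default_reporter_template("[GT]_10")


@pytest.fixture(scope="session")
def apc_ims_template():
    """Interrupted mononucleotide allele modeled on the APC gene iMS."""
    return default_reporter_template("[A]_3 T [A]_4", template_id="apc-ims")
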