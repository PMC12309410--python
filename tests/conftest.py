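import pytest

from seepflux import GUAYMAS_DEMO, load_reference


@pytest.fixture(scope="session")
def ucc():
    return load_reference("UCC")


@pytest.fixture(scope="session")
def paas():
    return load_reference("PAAS")


@pytest.fixture(scope="session")
def seawater():
    return load_reference("SEAWATER")


@pytest.fixture
def demo_params():
    return GUAYMAS_DEMO


@pytest.fixture
def noiseless_params():
    return GUAYMAS_DEMO.replace(noise_sd_frac=0.0, nh4_sd=0.0, temp_noise_sd=0.0)
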