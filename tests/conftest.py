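import pytest

from irisqc import optics


@pytest.fixture(scope="session")
def air_config():
    return optics.OpticsConfig.default(medium="air")


@pytest.fixture(scope="session")
def water_config():
    return optics.OpticsConfig.default(medium="water")


@pytest.fixture(scope="session")
def lut_air(air_config):
    return optics.build_lut(air_config)


@pytest.fixture(scope="session")
def lut_water(water_config):
    return optics.build_lut(water_config)
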