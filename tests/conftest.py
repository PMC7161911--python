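import numpy as np
import pytest

from cassava_gsua import crop_model as cm
from cassava_gsua import soil_water as sw
from cassava_gsua.gsp import default_gsp_values, load_gsp_distributions, load_gsp_specs
from cassava_gsua.pipeline import load_sites
from cassava_gsua.weather import generate_weather


@pytest.fixture(scope="session")
def sites():
    return load_sites()


@pytest.fixture(scope="session")
def warm_weather(sites):
    return generate_weather(sites["warm"], n_years=2, seed=101)


@pytest.fixture(scope="session")
def cool_weather(sites):
    return generate_weather(sites["cool"], n_years=2, seed=102)


@pytest.fixture(scope="session")
def soil_warm():
    return sw.load_soil_profile("warm")


@pytest.fixture(scope="session")
def soil_cool():
    return sw.load_soil_profile("cool")


@pytest.fixture(scope="session")
def gsp_specs():
    return load_gsp_specs()


@pytest.fixture(scope="session")
def gsp_dists():
    return load_gsp_distributions()


@pytest.fixture(scope="session")
def gsp_defaults():
    return default_gsp_values()


@pytest.fixture(scope="session")
def gsp_set(gsp_defaults):
    return cm.GSPSet(**gsp_defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
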