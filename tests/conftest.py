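import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from achromatium import datasets
from achromatium.carbonate import compute_constants


@pytest.fixture(scope="session")
def basin():
    """Basin surface water, June 2012 sampling."""
    return datasets.BASIN_JUNE_2012


@pytest.fixture(scope="session")
def basin_constants(basin):
    return compute_constants(basin.temperature_c, basin.salinity, "millero06")
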