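import numpy as np
import pytest

from ramanpheno.preprocess import PreprocessParams
from ramanpheno.quantify import BandDefinition
from ramanpheno.synth import (
    DEFAULT_WAVENUMBERS,
    default_kinetics,
    default_profiles,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_WAVENUMBERS


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def green(profiles):
    """Default green-leaf profile (B73)."""
    return profiles["B73"]


@pytest.fixture(scope="session")
def white(profiles):
    """Dark-grown chlorophyll-less tissue profile."""
    return profiles["B73-dark"]


@pytest.fixture(scope="session")
def band_1157():
    return BandDefinition("carotenoid_1157", 1157.0, 10.0)


@pytest.fixture(scope="session")
def candidate_bands():
    return [
        BandDefinition("carotenoid_1007", 1007.0, 10.0),
        BandDefinition("carotenoid_1157", 1157.0, 10.0),
        BandDefinition("carotenoid_1524", 1524.0, 10.0),
    ]


@pytest.fixture
def params():
    return PreprocessParams()
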