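import numpy as np
import pytest

from heatfit import TitrationExperiment, injection_heats
from heatfit import reference as ref


@pytest.fixture(scope="session")
def table():
    """Published thermodynamic constants for the hub system."""
    return ref.TABLE


@pytest.fixture(scope="session")
def multi_eq_scheme():
    return ref.multi_eq_scheme()


@pytest.fixture(scope="session")
def two_mode_scheme():
    return ref.two_mode_scheme()


@pytest.fixture(scope="session")
def ternary_scheme():
    return ref.ternary_scheme()


@pytest.fixture(scope="session")
def single_site_scheme():
    return ref.single_site_scheme("3")


@pytest.fixture
def standard_forward():
    """15 uM hub in the cell, 150 uM titrant in the syringe, 20 x 2 uL."""
    return TitrationExperiment.from_lab_units((15.0, 0.0, 0.0), (0.0, 150.0, 0.0))


@pytest.fixture
def standard_reverse():
    return TitrationExperiment.from_lab_units(
        (0.0, 15.0, 0.0), (150.0, 0.0, 0.0), direction_label="reverse"
    )


def noise_free_datasets(scheme, experiments):
    """(experiment, simulated isotherm) pairs at exact model heats."""
    return [(exp, injection_heats(exp, scheme)) for exp in experiments]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190101)
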