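import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from nihlsim import (CochleaParams, LesionModel, StimulusSpec,
                     build_control_map)
from nihlsim.placemap import PlaceFrequencyMap


@pytest.fixture(scope="session")
def params():
    return CochleaParams()


@pytest.fixture(scope="session")
def lesion_model():
    return LesionModel()


@pytest.fixture(scope="session")
def place_map():
    return PlaceFrequencyMap()


@pytest.fixture(scope="session")
def control_map(params):
    return build_control_map(params, seed=1)


@pytest.fixture(scope="session")
def vs105_wide():
    """105 dB SPL violet sweep over the full 2-20 kHz band."""
    return StimulusSpec("violet_sweep", 2, 20, 105, 1800, 10)


@pytest.fixture(scope="session")
def vs120_wide():
    return StimulusSpec("violet_sweep", 2, 20, 120, 1800, 10)


@pytest.fixture(scope="session")
def vs105_narrow():
    """105 dB SPL violet sweep restricted to 9-13 kHz."""
    return StimulusSpec("violet_sweep", 9, 13, 105, 1800, 10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
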