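import warnings

import numpy as np
import pytest

from lkcbm import Medium, media_presets
from lkcbm import synth

warnings.filterwarnings("ignore", category=UserWarning, module="cobra")


@pytest.fixture(scope="session")
def toy():
    """The full toy network plus its analytic ground truth."""
    return synth.make_toy_model()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def media(toy_model):
    return media_presets(toy_model)


@pytest.fixture(scope="session")
def minimal_glucose(media):
    return media["minimal_glucose"]


@pytest.fixture(scope="session")
def anaerobic_glucose(minimal_glucose):
    limits = dict(minimal_glucose.uptake_limits)
    limits["EX_o2_e"] = 0.0
    return Medium("anaerobic_glucose", limits, set(minimal_glucose.unrestricted))


@pytest.fixture(scope="session")
def semi_aerobic_glucose(minimal_glucose):
    limits = dict(minimal_glucose.uptake_limits)
    limits.update({"EX_o2_e": 3.0, "EX_glc__D_e": 2.28})
    return Medium("semi_aerobic_glucose", limits, set(minimal_glucose.unrestricted))
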