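import numpy as np
import pytest

from durinose.acquisition import PhaseSchedule
from durinose.catalog import GM_SENSORS


@pytest.fixture
def rng():
    return np.random.default_rng(20240621)


@pytest.fixture
def survey_schedule():
    return PhaseSchedule.survey()


@pytest.fixture
def prototype_schedule():
    return PhaseSchedule.prototype()


@pytest.fixture
def gm_channels():
    return list(GM_SENSORS)
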