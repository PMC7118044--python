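import numpy as np
import pytest

from petquant.core import (
    InputFunctionParams,
    fine_time_grid,
    input_function,
    study_frame_schedule,
)


@pytest.fixture(scope="session")
def schedule():
    return study_frame_schedule()


@pytest.fixture(scope="session")
def tgrid(schedule):
    return fine_time_grid(schedule)


@pytest.fixture(scope="session")
def input_params():
    return InputFunctionParams()


@pytest.fixture(scope="session")
def cp(tgrid, input_params):
    return input_function(input_params, tgrid)
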