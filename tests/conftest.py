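import logging

import numpy as np
import pytest

from lamella.datamodel import DiffractionCondition


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("lamella").setLevel(logging.WARNING)
    yield


@pytest.fixture
def d16_condition():
    """Measurement context of the reference instrument setup."""
    return DiffractionCondition(
        wavelength=4.47,
        mu=5.0,
        t=50.0,
        temperature=323.15,
        relative_humidity=0.98,
        d2o_fraction=0.08,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
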