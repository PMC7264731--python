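import numpy as np
import pytest

from chqdose.pkmodel import DEFAULT_PARAMS
from chqdose.population import Subject


@pytest.fixture(scope="session")
def params():
    """Shipped compound parameters (cl_adult pre-calibrated to 14-d t1/2)."""
    return DEFAULT_PARAMS


@pytest.fixture
def reference_adult():
    """75-kg adult with fully mature elimination pathways."""
    return Subject(
        subject_id=0, age=35.0, sex="male", weight=75.0,
        f_cyp3a4=1.0, f_cyp2c8=1.0, f_gfr=1.0,
    )


@pytest.fixture
def adult_70kg():
    return Subject(
        subject_id=0, age=40.0, sex="female", weight=70.0,
        f_cyp3a4=1.0, f_cyp2c8=1.0, f_gfr=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
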