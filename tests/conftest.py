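import logging

import numpy as np
import pytest

from hoxtimer import build_default_hoxd_locus, discretize
from hoxtimer.config import default_params

logging.getLogger("hoxtimer").setLevel(logging.ERROR)
logging.getLogger("hoxtimer.locus").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def wt_locus():
    return build_default_hoxd_locus()


@pytest.fixture(scope="session")
def wt_lattice(wt_locus):
    return discretize(wt_locus, 2_000)


@pytest.fixture(scope="session")
def shipped_params():
    return default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
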