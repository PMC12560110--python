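from pathlib import Path

import numpy as np
import pytest

from symcurate import SimParams, generate, make_worked_fixture

WORKED_DIR = Path(__file__).parent / "data" / "worked"


@pytest.fixture(scope="session")
def worked():
    return make_worked_fixture()


@pytest.fixture(scope="session")
def sim_default():
    """The default synthetic coinfection (seed 1), shared across tests."""
    return generate(SimParams(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
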