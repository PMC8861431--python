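import numpy as np
import pytest

from srpkpd.chamber import ChamberGeometry, TransportParams
from srpkpd.monolayer import MonolayerSetup
from srpkpd.params import cp506_cell_lines, cp506_chain


@pytest.fixture(scope="session")
def chain():
    return cp506_chain()


@pytest.fixture(scope="session")
def lines():
    return cp506_cell_lines()


@pytest.fixture()
def aerobic_setup():
    return MonolayerSetup()


@pytest.fixture()
def anoxic_setup():
    return MonolayerSetup(oxygen_uM=0.0)


@pytest.fixture()
def geometry():
    return ChamberGeometry()


@pytest.fixture()
def transport_truth():
    return TransportParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
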