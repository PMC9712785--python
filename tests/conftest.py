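import numpy as np
import pytest

from spongenet import datasets


@pytest.fixture(scope="session")
def circ_records():
    return datasets.load_circrna_de()


@pytest.fixture(scope="session")
def mirna_records():
    return datasets.load_mirna_de()


@pytest.fixture(scope="session")
def hub_edges():
    return datasets.load_hub_interactions()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
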