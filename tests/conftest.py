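import numpy as np
import pytest

from fretloop.trajectory import Frame, LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_labels():
    """Label map for a 10-atom toy molecule."""
    return LabelMap(
        indole_bond=(0, 1),
        diazo_group=(8, 9),
        donor_dipole=(0, 1),
        acceptor_dipole=(8, 9),
        terminal_ca=(0, 9),
        heavy_atoms=tuple(range(10)),
        masses=np.ones(10),
    )


@pytest.fixture
def random_frame(rng):
    return Frame(rng.normal(size=(10, 3)), time=0.0)
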