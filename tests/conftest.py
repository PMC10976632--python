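import numpy as np
import pytest
from hypothesis import settings

from wbpremd import calibrate_model, quadrature_state_probabilities
from wbpremd.model import STATE_ORDER
from wbpremd.synthetic import reference_state_table

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_table():
    return reference_state_table()


@pytest.fixture(scope="session")
def calibrated_model(reference_table):
    """Toy model calibrated so its octant free energies match the reference table."""
    return calibrate_model(reference_table.free_energies)


@pytest.fixture(scope="session")
def calibrated_probs(calibrated_model):
    return dict(zip(STATE_ORDER,
                    quadrature_state_probabilities(calibrated_model, grid_points=160)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
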