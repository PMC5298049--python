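import numpy as np
import pytest

from cawave.agonist import SigmoidSpec, sigmoid_map
from cawave.cell_models import ModelParameters, rest_state
from cawave.coupling import build_adjacency, coupling_case
from cawave.geometry import GeometrySpec, build_tube, tile_cells


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def rest(params):
    """Isolated-cell rest state at zero agonist."""
    return rest_state(params)


@pytest.fixture(scope="session")
def rest_y(rest):
    ec, smc = rest
    return np.concatenate([ec.to_array(), smc.to_array()])


@pytest.fixture(scope="session")
def mini_tube():
    """2 x 4 quad tube: 8 domains, 640 EC + 1664 SMC."""
    spec = GeometrySpec(branch_length=0.52, diameter=0.26,
                        quads_axial=2, quads_circ=4)
    return tile_cells(build_tube(spec))


@pytest.fixture(scope="session")
def mini_adjacency(mini_tube):
    return build_adjacency(mini_tube)


@pytest.fixture(scope="session")
def mini_agonist(mini_tube):
    spec = SigmoidSpec(j_min=2.0, j_max=5.0,
                       x_center=float(mini_tube.ec.axial.mean()),
                       steepness=5.0)
    return sigmoid_map(mini_tube, spec)


@pytest.fixture(scope="session")
def case1():
    return coupling_case(1)
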