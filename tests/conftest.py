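import numpy as np
import pytest

from aclfem.geometry import make_tunnel_family
from aclfem.meshing import Mesh


@pytest.fixture(scope="session")
def tunnel_family():
    """The study's five constant-area femoral tunnel sections."""
    return make_tunnel_family(8.0, [2.0, 4.0, 6.0, 8.0])


@pytest.fixture
def unit_hex_mesh():
    nodes = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    return Mesh(
        nodes=nodes,
        element_type="hex8",
        elements=np.array([[0, 1, 2, 3, 4, 5, 6, 7]]),
        region=np.array(["graft"]),
    )


@pytest.fixture
def unit_tet_mesh():
    nodes = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
    )
    return Mesh(
        nodes=nodes,
        element_type="tet4",
        elements=np.array([[0, 1, 2, 3]]),
        region=np.array(["cancellous"]),
    )
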