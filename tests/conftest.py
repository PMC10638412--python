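import numpy as np
import pytest

import axonrve as ax


@pytest.fixture(scope="session")
def cc_structural():
    """Corpus-callosum histology parameters (aligned fibers)."""
    return ax.corpus_callosum_params()


@pytest.fixture(scope="session")
def cc_matrix_penalty():
    """Identified matrix constants with the nearly incompressible penalty."""
    mp, _ = ax.corpus_callosum_materials()
    return mp


@pytest.fixture(scope="session")
def cc_matrix_incompressible():
    return ax.MatrixParams(353.5, -21.5, None)


@pytest.fixture(scope="session")
def cc_fibers():
    return ax.FiberParams(80.8, 62.3)


@pytest.fixture(scope="session")
def small_mesh():
    """5 µm cube at the reference element size (64 hexes)."""
    return ax.build_mesh(5.0, 1.25)


@pytest.fixture(scope="session")
def aligned_network_25(cc_structural):
    """One 25 µm corpus-callosum network, fixed seed."""
    return ax.generate_rve(cc_structural, 25.0, seed=42)


@pytest.fixture(scope="session")
def single_fiber_network():
    """One axis-aligned straight fiber through a 5 µm cube (dilute limit)."""
    net = ax.FiberNetwork(
        La=5.0,
        anchor=np.array([[0.0, 2.1875, 2.1875]]),
        N=np.array([[1.0, 0.0, 0.0]]),
        L0=np.array([5.0]),
        d=np.array([0.3]),
        Ps=np.array([1.0]),
        seed=0,
    )
    net.achieved_vf = ax.network_volume_fraction(net)
    return net
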