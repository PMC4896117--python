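import numpy as np
import pytest

from bulksurf.mesh import DomainSpec, generate_initial_mesh


@pytest.fixture(scope="session")
def disc_mesh_h01():
    """Unit-disc mesh with target edge length 0.1 (shared, do not mutate)."""
    return generate_initial_mesh(DomainSpec("disc", h=0.1), seed=0)


@pytest.fixture(scope="session")
def cell_annulus_mesh():
    """Small cell-in-circle annulus (r0=0.1, rf=0.3), membrane-graded."""
    return generate_initial_mesh(
        DomainSpec("annulus_cell_in_circle", h=0.035, r0=0.1, rf=0.3,
                   h_min=0.012, ns_inner=80), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
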