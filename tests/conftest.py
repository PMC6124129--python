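import numpy as np
import pytest

from dlcm import assemble_laplacian, build_structured_grid, initialize_state


@pytest.fixture
def grid5():
    """5x5 Cartesian grid with h = 1."""
    return build_structured_grid("cartesian2d", (5, 5), h=1.0)


@pytest.fixture
def strip_state(grid5):
    """The hand-solved 1x3 strip: u = (1, 2, 1) along the centre row,
    everything else empty.  Voxel ids (11, 12, 13) are (A, B, C)."""
    occ = np.zeros(grid5.n_voxels, dtype=np.int64)
    occ[11], occ[12], occ[13] = 1, 2, 1
    return initialize_state(grid5, occ)


@pytest.fixture
def laplacian5(grid5):
    return assemble_laplacian(grid5)


def random_occupancy(grid, rng, p_occupied=0.5, p_double=0.3):
    """Random occupancy with at least one empty voxel and one source."""
    occ = np.zeros(grid.n_voxels, dtype=np.int64)
    occupied = rng.random(grid.n_voxels) < p_occupied
    occ[occupied] = 1
    occ[occupied & (rng.random(grid.n_voxels) < p_double)] = 2
    occ[0] = 0  # guarantee a free boundary
    if not (occ == 2).any():
        ones = np.flatnonzero(occ == 1)
        occ[ones[0] if ones.size else 1] = 2
    return occ
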