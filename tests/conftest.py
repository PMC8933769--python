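import numpy as np
import pytest

from amypet.volumes import DEFAULT_GRID, Grid3D
from amypet.synthetic import CohortGenerator, make_voi_set, make_wm_mask


def centered_grid(dims, voxel_mm):
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * np.asarray(dims) / 2.0
    return Grid3D(dims=dims, affine=aff)


@pytest.fixture(scope="session")
def small_grid():
    """A 48x56x48 grid at 4 mm — big enough for the synthetic brain,
    cheap enough for per-test pipelines."""
    return centered_grid((48, 56, 48), 4.0)


@pytest.fixture(scope="session")
def small_vs(small_grid):
    return make_voi_set(small_grid)


@pytest.fixture(scope="session")
def small_wm(small_grid):
    return make_wm_mask(small_grid)


@pytest.fixture(scope="session")
def default_vs():
    return make_voi_set(DEFAULT_GRID)


@pytest.fixture(scope="session")
def small_gen(small_grid):
    """Cohort generator on the small grid, with a cached normative DB."""
    return CohortGenerator(grid=small_grid, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
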