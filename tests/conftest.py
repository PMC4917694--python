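import numpy as np
import pytest

from kcmap.maps import PolarGrid, ThicknessMap
from kcmap.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_grid():
    """Coarse 16x32 grid for oracle-enumeration tests."""
    radii = np.arange(1, 17) * (3.0 / 16)
    angles = np.arange(32) * (360.0 / 32)
    return PolarGrid(radii, angles)


@pytest.fixture
def uniform_map(toy_grid):
    return ThicknessMap(toy_grid, np.full((16, 32), 540.0), 540.0, tag="pachymetry")


def random_map(grid, rng, lo=480.0, hi=580.0, tag="pachymetry"):
    vals = rng.uniform(lo, hi, size=(grid.n_radii, grid.n_angles))
    return ThicknessMap(grid, vals, float(rng.uniform(lo, hi)), tag=tag)


@pytest.fixture(scope="session")
def small_cohort():
    """Map-level cohort shared across tests (10 healthy + 6 KC subjects)."""
    return generate_cohort(
        CohortSpec(n_normal_subjects=10, n_asym_kc_subjects=6, seed=3,
                   n_radii=32, n_angles=64)
    )
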