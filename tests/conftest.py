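import numpy as np
import pytest

from convstate.config import CohortSpec


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A scaled-down cohort for fast unit tests (structure preserved)."""
    return CohortSpec(
        n_subjects=4,
        n_runs=3,
        trials_per_condition_per_run=6,
        n_voxels_by_roi={"VTA": 20, "HPC": 40, "PHC": 15, "PRC": 15},
        n_grid_voxels=100,
        n_coupled_voxels=10,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
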