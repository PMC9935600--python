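"""Shared fixtures: small synthetic subjects and projection stacks.

Everything is generated programmatically and seeded; the heavier cohort
fixtures are session-scoped so the simulation cost is paid once.
"""

import numpy as np
import pytest

from spectden.cv_harness import build_cohort, toy_config
from spectden.phantom import CohortSpec, make_phantom
from spectden.projector import AcquisitionSpec, add_poisson, forward_project


@pytest.fixture(scope="session")
def small_cohort_cfg():
    """Ten toy-scale subjects (32^3 phantoms, 16-view 16x16 stacks)."""
    return toy_config(seed=11, n_subjects=10)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_cfg):
    return build_cohort(small_cohort_cfg)


@pytest.fixture(scope="session")
def phantom24():
    spec = CohortSpec(n_subjects=3, grid_shape=(24, 24, 24), voxel_size_cm=0.8,
                      defect_fraction=1.0, rng_seed=3)
    return make_phantom(spec, 0)


@pytest.fixture(scope="session")
def noisy_stack(phantom24):
    acq = AcquisitionSpec(n_views=8, mean_counts_per_view_at_full_time=5e4)
    return add_poisson(forward_project(phantom24, acq), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
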