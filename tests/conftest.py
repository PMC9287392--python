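"""Shared fixtures: small phantoms and one fully processed cohort.

Phantoms use a reduced field of view (the orbit region only) so the whole
suite runs on one CPU in minutes; acquisition parameters (48 directions at
b = 2000, 2 mm voxels, two opposed-phase b0s) stay at their defaults.
"""

import numpy as np
import pytest

from ondti.dwi_core import merge_b0_pairs
from ondti.phantom import CohortSpec, PhantomSpec, make_phantom
from ondti.pipeline import run_cohort
from ondti.tensor_fit import fit_tensor_lls, scalar_maps

STRAIGHT_CTRL = ((19.0, 7.0, 15.0), (19.0, 31.0, 15.0))


@pytest.fixture(scope="session")
def straight_spec():
    """Straight 24 mm tube along +y, noiseless, small grid."""
    return PhantomSpec(
        grid_shape=(20, 20, 16),
        snr=np.inf,
        seed=0,
        centerline_ctrl_points=STRAIGHT_CTRL,
    )


@pytest.fixture(scope="session")
def straight_bundle(straight_spec):
    return make_phantom(straight_spec)


@pytest.fixture(scope="session")
def straight_tf(straight_bundle):
    return fit_tensor_lls(merge_b0_pairs(straight_bundle.dataset))


@pytest.fixture(scope="session")
def straight_maps(straight_tf):
    return scalar_maps(straight_tf)


@pytest.fixture(scope="session")
def healthy_spec():
    """Curved healthy-profile nerve at SNR 20 on the reduced grid."""
    return PhantomSpec(grid_shape=(32, 32, 24), snr=20.0, seed=1)


@pytest.fixture(scope="session")
def healthy_bundle(healthy_spec):
    return make_phantom(healthy_spec)


@pytest.fixture(scope="session")
def healthy_result(healthy_bundle):
    """Full default-parameter pipeline run on the healthy curved phantom."""
    from ondti.pipeline import process_nerve

    return process_nerve(healthy_bundle.dataset, *healthy_bundle.rois, seed=3)


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec(phantom=PhantomSpec(grid_shape=(32, 32, 24)), seed=11)


@pytest.fixture(scope="session")
def cohort_df(cohort_spec):
    """Fully processed 34-nerve cohort (simulation + pipeline + summaries)."""
    return run_cohort(cohort_spec)
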