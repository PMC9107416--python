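import numpy as np
import pytest

from falffmvpa.roi import ROIDefinition, ROISet
from falffmvpa.synth import CohortSpec, cohort_features, generate_cohort


def centered_affine(shape, voxel_size=3.0):
    """RAS affine putting MNI (0,0,0) at the grid centre."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return affine


ROI_NAMES = tuple(f"ROI{i:02d}" for i in range(8))


@pytest.fixture(scope="session")
def null_features():
    """17+17 subjects, 8 ROI features, no injected effect (series mode)."""
    spec = CohortSpec(n_per_group=17, rois=ROI_NAMES, effect_size=1.0, seed=20260929)
    return cohort_features(generate_cohort(spec))


@pytest.fixture(scope="session")
def effect_features():
    """17+17 subjects, effect_size=2 in 3 of 8 ROIs."""
    spec = CohortSpec(n_per_group=17, rois=ROI_NAMES,
                      effect_rois=("ROI00", "ROI01", "ROI02"),
                      effect_size=2.0, seed=7)
    return cohort_features(generate_cohort(spec))


@pytest.fixture
def small_grid_roiset():
    """Three spheres comfortably inside a 12^3 grid at 3 mm."""
    return ROISet([
        ROIDefinition("A", center=(0.0, 0.0, 0.0), radius=4.0),
        ROIDefinition("B", center=(-9.0, 9.0, 0.0), radius=4.0),
        ROIDefinition("C", center=(9.0, -9.0, -9.0), radius=4.0),
    ])
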