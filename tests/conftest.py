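import numpy as np
import pytest

from morphnet import (
    CohortConfig,
    GreyMatterMap,
    Parcellation,
    build_mc_matrix,
    extract_roi_samples,
    generate_cohorts,
)


@pytest.fixture
def two_roi_parcellation():
    """200 voxels split into two 100-voxel ROIs (flat raster blocks)."""
    labels = np.zeros((2, 10, 10), dtype=np.int16)
    labels.ravel()[:100] = 1
    labels.ravel()[100:] = 2
    return Parcellation(labels=labels, roi_catalogue=[(1, "left"), (2, "right")])


@pytest.fixture
def uniform_map(two_roi_parcellation):
    vol = np.full((2, 10, 10), 0.5)
    return GreyMatterMap(subject_id="uniform", volume=vol)


@pytest.fixture
def small_cohort_config():
    """8 ROIs, 6+6 subjects, no injected effects — a fast null cohort."""
    return CohortConfig(
        n_rois=8,
        grid_shape=(8, 8, 8),
        n_per_group=(6, 6),
        seed=11,
    )


def cohort_mc_stack(config: CohortConfig) -> tuple[np.ndarray, list[int], object]:
    """Generate a cohort and compute its (n_subjects, N, N) MC stack."""
    cohort = generate_cohorts(config)
    stack = []
    for gm in cohort.maps:
        samples = extract_roi_samples(gm, cohort.parcellation)
        stack.append(build_mc_matrix(samples, gm.subject_id).values)
    return np.stack(stack), cohort.parcellation.roi_ids, cohort
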