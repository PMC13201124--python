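import numpy as np
import pytest

from ith3d.cohorts import CohortSpec, make_cohort, split_cohort
from ith3d.ensemble import PipelineConfig, fast_grids, train_stack
from ith3d.phantoms import make_phantom, separable_phantom_spec


@pytest.fixture(scope="session")
def cohort600():
    """Planted-signal cohort at the study prevalence, three centers."""
    return make_cohort(CohortSpec(n=600, prevalence=0.134, seed=11,
                                  center_proportions=(0.35, 0.35, 0.30)))


@pytest.fixture(scope="session")
def dev_ext(cohort600):
    return split_cohort(cohort600)


@pytest.fixture(scope="session")
def fast_config():
    return PipelineConfig(seed=7, grids=fast_grids())


@pytest.fixture(scope="session")
def trained_stack(dev_ext, fast_config):
    """One stack fitted on the development split, shared across tests."""
    dev, _ = dev_ext
    return train_stack(dev, fast_config)


@pytest.fixture(scope="session")
def separable_phantom():
    """One fragmented separable phantom with its planted label map."""
    spec = separable_phantom_spec(6, fragments=(1, 1, 1, 1, 2, 2), seed=5)
    return make_phantom(spec)


def crop_ground_truth(lesion, label_map, margin=1):
    """Planted labels cropped with the same bounding box as the lesion."""
    zz = np.argwhere(lesion.mask)
    lo = np.maximum(zz.min(0) - margin, 0)
    hi = np.minimum(zz.max(0) + 1 + margin, lesion.mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return label_map.labels[sl]
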