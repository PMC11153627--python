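import numpy as np
import pandas as pd
import pytest

from molnorm.synthetic_data import (
    SyntheticConfig,
    inject_deviations,
    make_atlas,
    make_cohort,
    make_ground_truth,
    make_templates,
    simulate_roi_matrix,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast two-site, three-system study used across module tests."""
    return SyntheticConfig(
        seed=11,
        n_voxels_per_axis=10,
        n_systems=3,
        n_timepoints=80,
        n_rois=24,
        n_subjects_per_site={"siteA": 40, "siteB": 40},
        n_patients_per_group={"G1": 15, "G2": 15, "G3": 15},
    )


@pytest.fixture(scope="session")
def templates(small_config):
    return make_templates(small_config)


@pytest.fixture(scope="session")
def atlas(small_config):
    return make_atlas(small_config)


@pytest.fixture(scope="session")
def cohort(small_config) -> pd.DataFrame:
    return make_cohort(small_config)


@pytest.fixture(scope="session")
def truth(small_config, templates):
    return make_ground_truth(small_config, templates)


@pytest.fixture(scope="session")
def roi_matrix(small_config, cohort, truth):
    """ROI-level FC with planted patient deviations injected."""
    base = simulate_roi_matrix(cohort, truth, small_config)
    return inject_deviations(base, cohort, truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
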