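import numpy as np
import pytest

from unbgcn import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small effect-bearing cohort shared by biomarker-level tests."""
    cfg = CohortConfig(
        n_ad=20,
        n_mci=15,
        n_cu=25,
        n_rois=6,
        vertices_per_roi=30,
        atrophy_effect_ad=0.5,
        atrophy_effect_mci=0.25,
        noise_sd=0.15,
        affected_roi_fraction=0.5,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
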