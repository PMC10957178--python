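import numpy as np
import pytest

from morphlink import (
    SyntheticCohortSpec,
    gen_cohort,
    gen_connectome,
    gen_smooth_map,
    gen_sphere_parcellation,
)


@pytest.fixture(scope="session")
def geometry200():
    return gen_sphere_parcellation(200, seed=0)


@pytest.fixture(scope="session")
def geometry100():
    return gen_sphere_parcellation(100, seed=0)


@pytest.fixture(scope="session")
def distances200(geometry200):
    return geometry200.distances()


@pytest.fixture(scope="session")
def smooth_map200(geometry200):
    return gen_smooth_map(geometry200, 50.0, seed=11)


@pytest.fixture(scope="session")
def connectome200(geometry200):
    return gen_connectome(geometry200, density=0.15, n_modules=2, module_boost=8.0, seed=3)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Strong planted coupling, no confounds/missingness: clean recovery."""
    spec = SyntheticCohortSpec(
        n_subjects=2000, n_regions=60, n_clinical=12,
        coupling_strength=0.8, noise_sd=0.5,
        missing_rate=0.0, confound_strength=0.0, seed=21,
    )
    return gen_cohort(spec)
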