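import numpy as np
import pytest

from dcehabitat.model import BiExpFit
from dcehabitat.pipeline import RunConfig
from dcehabitat.synthetic import CohortConfig, generate_patient

# a small, fast geometry used by most volume-level tests
SMALL = dict(
    grid_shape=(32, 32, 24),
    voxel_spacing=(2.0, 2.0, 2.0),
    prostate_semi_axes=(14.0, 12.0, 10.0),
    lesion_radius_mm=(3.5, 5.0),
)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_patients=4, seed=11, **SMALL)


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    return CohortConfig(n_patients=2, seed=11, noise_sigma=0.0,
                        adc_noise_sigma=0.0, **SMALL)


@pytest.fixture(scope="session")
def patient(small_config) -> object:
    return generate_patient(small_config, 0)


@pytest.fixture(scope="session")
def noiseless_patient(noiseless_config) -> object:
    return generate_patient(noiseless_config, 0)


@pytest.fixture(scope="session")
def small_run_config() -> RunConfig:
    return RunConfig(seed=11, n_patients=8, run_quadruples=False,
                     cohort_overrides=dict(SMALL))


def random_valid_params(rng: np.random.Generator) -> BiExpFit:
    """A random parameter set in the physiologically sensible ranges."""
    k_out = rng.uniform(0.001, 0.02)
    k_in = rng.uniform(max(3.0 * k_out, 0.02), 0.3)
    return BiExpFit(
        s0=rng.uniform(-0.5, 1.0),
        A=rng.uniform(0.5, 2.0),
        t0=rng.uniform(10.0, 60.0),
        k_in=k_in,
        k_out=k_out,
    )
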