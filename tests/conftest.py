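import numpy as np
import pytest

from pvsmap import CohortSpec, build_registry, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless phantom with a handful of tubes, for fast end-to-end checks."""
    return generate_phantom(shape=(48, 48, 10), n_pvs=10, contrast=120.0,
                            noise_sd=0.0, bias_amplitude=0.05, seed=11)


@pytest.fixture(scope="session")
def table1_cohort():
    """Cohort with the default (emulated Table-1) marginals, null effects."""
    return generate_cohort(CohortSpec(seed=5, sex_effect=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
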