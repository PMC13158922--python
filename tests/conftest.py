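import logging

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from porphkin.fitting import FitOptions
from porphkin.synthetic_data import (
    DEFAULT_TRUTH,
    NoiseModel,
    default_design,
    generate_dataset,
)

# fortran lsoda chatter and penalty-residual warnings are expected during
# multistart sweeps; keep the test log readable
logging.getLogger("porphkin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def truth():
    return DEFAULT_TRUTH


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_dataset(DEFAULT_TRUTH, noise=NoiseModel(cv=0.0, floor=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_dataset(DEFAULT_TRUTH, noise=NoiseModel(cv=0.05, seed=1))


@pytest.fixture(scope="session")
def quick_options():
    """Lean but reliable fit configuration for unit tests."""
    return FitOptions(n_starts=4, seed=0, rtol=1e-7, atol=1e-11)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_dataset, quick_options):
    from porphkin.fitting import fit_model

    return fit_model(noiseless_dataset, quick_options)


@pytest.fixture(scope="session")
def noisy_fit(noisy_dataset, quick_options):
    from porphkin.fitting import fit_model

    return fit_model(noisy_dataset, quick_options)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
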