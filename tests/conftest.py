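import warnings

import numpy as np
import pytest

from cb1rquant import evaluate, synthgen
from cb1rquant.core import StackGeometry

# the statistics of tiny simulated cohorts legitimately produce empty-cell
# warnings; keep test output readable
warnings.filterwarnings("ignore", message="dropping .* empty")


@pytest.fixture(scope="session")
def small_geometry() -> StackGeometry:
    return evaluate.small_test_geometry()


@pytest.fixture
def quiet_params():
    """Noise-free, attenuation-free, single-exposure generator settings."""

    def make(**overrides):
        overrides.setdefault("gaussian_sd", 0.0)
        overrides.setdefault("poisson_scale", 0.0)
        overrides.setdefault("depth_attenuation_rate", 0.0)
        overrides.setdefault("reference_exposure_ms", 25.0)
        return evaluate.small_test_params(**overrides)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
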