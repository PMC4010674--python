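import numpy as np
import pytest

from fielddcm import (
    ConditionDesign,
    SpectralGrid,
    build_model_space,
    default_priors,
    materialise,
)
from fielddcm.experiments import reduced_priors  # noqa: F401  (shared study setup)


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def prior_mean_params(priors):
    """(syn, conn, sensors, noise) at the prior means."""
    return materialise(priors, {})


@pytest.fixture(scope="session")
def design():
    return ConditionDesign.study()


@pytest.fixture(scope="session")
def small_grid():
    return SpectralGrid.default(freqs=np.linspace(4.0, 90.0, 24), n_modes=16)


@pytest.fixture(scope="session")
def model7():
    return build_model_space()[6]


def draw_within_prior(rng, priors, scale=3.0):
    """Random deviations within +-scale prior standard deviations."""
    return {
        name: rng.uniform(-scale, scale) * np.sqrt(priors[name].logvar)
        for name in priors.free_names
    }
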