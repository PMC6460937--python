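import numpy as np
import pytest

from netmosaic.config import SimulationConfig
from netmosaic.cohort import generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small cohort: 5 subjects/sex on a 12x12x8 grid, 3 network + 2
    artefact sources, with an F>M effect planted on source 0."""
    return SimulationConfig(
        n_subjects_per_sex=5,
        n_timepoints=40,
        grid_shape=(12, 12, 8),
        n_neural_sources=3,
        n_noise_sources=2,
        sex_effect_betas={0: [0.8]},
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
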