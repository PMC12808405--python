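import numpy as np
import pytest

from cohortlink.simulate import SimulationConfig, demo_effects, generate_study

SMALL_N_ANALYTES = {
    "blood_cells": 8,
    "colonic_cells": 8,
    "fecal_microbes": 15,
    "colonic_microbes": 12,
}


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_analytes=dict(SMALL_N_ANALYTES))


@pytest.fixture(scope="session")
def small_study(small_config):
    """A reduced-size study with the demo planted effects."""
    return generate_study(small_config, demo_effects(small_config))


@pytest.fixture(scope="session")
def null_study(small_config):
    """Same design, no planted effects."""
    return generate_study(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
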