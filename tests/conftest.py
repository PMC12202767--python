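import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from hotspot_assembly import (
    RunConfig,
    default_pair_scenario,
    study_strain_truths,
)
from hotspot_assembly.synthetic_data import NoiseModel, ScenarioConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_scenario():
    """Default two-strain null scenario at the study's conditions."""
    return default_pair_scenario(seed=7)


@pytest.fixture
def zero_noise_scenario():
    """Noise-free pair scenario in the pure exponential growth regime.

    Self-consistency is exact only while curves stay exponential over the
    fitted window, so the carrying capacity is lifted.
    """
    truths = {
        t.strain_id: dataclasses.replace(t, carrying_od=float("inf"))
        for t in study_strain_truths()
    }
    return ScenarioConfig(
        strains=[truths["HF66"], truths["HF9B"]],
        initial_fractions=[0.6, 0.4],
        noise=NoiseModel.none(),
        rng_seed=0,
    )
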