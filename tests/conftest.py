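import numpy as np
import pytest
from hypothesis import settings

from trailside import synthetic as syn

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    return syn.make_design(syn.SimConfig(seed=42, n_pairs=4, n_quadrats=4))


@pytest.fixture(scope="session")
def full_design():
    return syn.make_design(syn.SimConfig(seed=42))


def make_species(
    b0=3.0,
    bD=-0.5,
    bE=0.0,
    bDE=0.0,
    nb_shape=5.0,
    sigma_pair=0.3,
    lambda_rep=0.05,
    occupancy=0.53,
    name="test-species",
):
    eff = syn.TraitEffects(b0, bD, bE, bDE)
    return syn.SpeciesParams(
        name=name,
        height=eff,
        diameter=eff,
        nb_shape=nb_shape,
        sigma_pair=sigma_pair,
        lambda_rep=lambda_rep,
        occupancy=occupancy,
    )
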