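import numpy as np
import pytest
from hypothesis import settings

from thermosens import (
    DesignSpec,
    TruthSpec,
    default_binning,
    default_fakhouri_space,
    default_zinzen_space,
    make_fakhouri_constructs,
    make_repressor_gradient,
    make_objective,
    make_zinzen_profiles,
    simulate_dataset,
    zinzen_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def binning():
    return default_binning()


@pytest.fixture(scope="session")
def fak_space():
    return default_fakhouri_space()


@pytest.fixture(scope="session")
def original_design(binning):
    return make_fakhouri_constructs(DesignSpec("original"), binning)


@pytest.fixture(scope="session")
def gradient():
    return make_repressor_gradient(11)


@pytest.fixture(scope="session")
def fak_truth():
    return TruthSpec(placement="mid-range", noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def fak_dataset(original_design, fak_truth, gradient, binning, fak_space):
    return simulate_dataset(original_design.constructs, fak_truth, gradient, binning, fak_space)


@pytest.fixture(scope="session")
def fak_objective(fak_dataset, fak_space):
    return make_objective(fak_dataset, "fakhouri", fak_space, kind="rmse")


@pytest.fixture(scope="session")
def zin_space():
    return default_zinzen_space()


@pytest.fixture(scope="session")
def zin_profiles(zin_space):
    return make_zinzen_profiles(60, seed=1, space=zin_space, noise_sd=0.0, set_index=0)


@pytest.fixture(scope="session")
def zin_objective(zin_profiles, zin_space):
    return make_objective(zinzen_dataset(zin_profiles), "zinzen", zin_space, kind="pearson")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
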