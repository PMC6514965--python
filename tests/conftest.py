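import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

warnings.filterwarnings("ignore", module="MDAnalysis")

from capscan import ElectrostaticParams, ToyCapsomerSpec, make_mode_pair, make_toy_capsomer


@pytest.fixture(scope="session")
def toy_spec():
    return ToyCapsomerSpec()


@pytest.fixture(scope="session")
def toy(toy_spec):
    return make_toy_capsomer(toy_spec)


@pytest.fixture(scope="session")
def mode_pairs(toy_spec):
    return {mode: make_mode_pair(mode, toy_spec) for mode in (1, 2, 3)}


@pytest.fixture(scope="session")
def dh_params():
    """Default screened-Coulomb model: 0.15 M salt, eps 80."""
    return ElectrostaticParams()


@pytest.fixture(scope="session")
def coulomb_params():
    return ElectrostaticParams(model="coulomb_uniform", ionic_strength=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190416)
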