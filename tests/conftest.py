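import warnings

import numpy as np
import pytest

from bustedmh import (
    BustedModel,
    ModelConfig,
    get_code,
)
from bustedmh.simulate import null_spec, simulate_alignment

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*overfitting.*")


@pytest.fixture(scope="session")
def code():
    return get_code()


@pytest.fixture(scope="session")
def small_sim():
    """Small 4-taxon replicate with both 2H and 3H events."""
    spec = null_spec(delta=0.25, psi=0.1, seed=11, n_codons=150)
    return simulate_alignment(spec)


@pytest.fixture(scope="session")
def small_fit_pair(small_sim):
    """+S alternative/null fit pair on the small replicate."""
    from bustedmh.inference import fit_eds_pair
    model = BustedModel(small_sim.alignment, small_sim.spec.tree,
                        config=ModelConfig.s())
    return fit_eds_pair(model, starts=1, seed=0, effort=0.6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
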