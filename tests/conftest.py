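import numpy as np
import pytest

from popcongruence import synth
from popcongruence.data_model import TrialTimeline


@pytest.fixture(scope="session")
def msmt_small():
    """One MSMT session, 25 units, default mixture."""
    spec = synth.PopulationGenSpec(n_units=25, n_sessions=1, seed=11)
    return synth.generate_population(spec, "MSMT")


@pytest.fixture(scope="session")
def bsmt_small():
    """Two BSMT sessions, 20 units."""
    spec = synth.PopulationGenSpec(n_units=20, n_sessions=2, seed=12)
    return synth.generate_population(spec, "BSMT")


@pytest.fixture(scope="session")
def compositional_small():
    """Additive (kappa=0), person-exchangeable compositional population."""
    spec = synth.CompositionalSpec(n_units=60, n_sessions=1, kappa=0.0, seed=13)
    exp, latents = synth.generate_compositional_population(spec)
    return exp, latents


@pytest.fixture(scope="session")
def timeline():
    return TrialTimeline()
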