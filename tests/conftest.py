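import numpy as np
import pytest

from fretcycle.models import CorrectionSet, TwoStateKineticModel
from fretcycle.simulate import SimBurstConfig, simulate_photon_stream


@pytest.fixture(scope="session")
def identity_corrections():
    return CorrectionSet.identity()


@pytest.fixture(scope="session")
def realistic_corrections():
    """Truth corrections used by the forward simulator throughout."""
    return CorrectionSet(alpha=0.05, beta=0.15, gamma=0.8, background_rates=(0.3, 0.2, 0.5))


@pytest.fixture(scope="session")
def dynamic_stream(realistic_corrections):
    """A medium-sized stream of a 0.2/0.9 dimer hopping at 0.5 ms^-1."""
    model = TwoStateKineticModel(E1=0.2, E2=0.9, k12=0.5, k21=0.5)
    cfg = SimBurstConfig(n_bursts=800, truth_corrections=realistic_corrections, seed=11)
    return simulate_photon_stream(model, cfg)
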