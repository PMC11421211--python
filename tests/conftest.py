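import numpy as np
import pytest

from synbio_forge import RngKey
from synbio_forge.circuit import (
    CircuitParams,
    GeneCircuit,
    StepInput,
    incoherent_feedforward,
    single_gene,
)


@pytest.fixture
def key() -> RngKey:
    return RngKey.from_seed(1234)


@pytest.fixture
def linear_gene() -> GeneCircuit:
    """Unregulated input-driven gene: dx/dt = beta*u - gamma*x (closed form)."""
    T, tgt, out = single_gene()
    params = CircuitParams(beta=np.array([2.0]), gamma=np.array([1.0]),
                           K=np.ones((1, 1)), n_hill=np.full((1, 1), 2.0))
    return GeneCircuit.from_params(T, tgt, out, params)


@pytest.fixture
def step_input() -> StepInput:
    return StepInput(u1=1.0, u2=1.5, t_step=50.0, t_end=100.0)


@pytest.fixture
def iffl():
    return incoherent_feedforward()
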