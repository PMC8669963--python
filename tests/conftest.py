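import numpy as np
import pytest

from dbskuramoto import (
    CouplingMatrix,
    OscillatorEnsemble,
    PlasticitySignature,
    SimulationState,
    StimulusSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_spec():
    return StimulusSpec()


@pytest.fixture
def zero_coupling_state():
    """n=4 state with zero coupling and simple frequencies/phases."""
    n = 4
    # dyadic frequencies so repeated addition equals omega * t exactly
    omega = np.array([0.25, 0.5, 0.125, 0.0625])
    phases = np.zeros(n)
    ens = OscillatorEnsemble(n=n, natural_frequencies=omega, phases=phases)
    coupling = CouplingMatrix(
        n=n,
        strengths=np.zeros((n, n)),
        draws_r1=np.zeros((n, n)),
        draws_r2=np.zeros((n, n)),
    )
    return SimulationState(iteration=0, ensemble=ens), coupling


def make_state(omega, phases, iteration=0):
    omega = np.asarray(omega, float)
    phases = np.asarray(phases, float)
    ens = OscillatorEnsemble(n=len(omega), natural_frequencies=omega, phases=phases)
    return SimulationState(iteration=iteration, ensemble=ens)


def make_coupling(strengths):
    k = np.asarray(strengths, float)
    n = k.shape[0]
    return CouplingMatrix(
        n=n, strengths=k, draws_r1=np.zeros((n, n)), draws_r2=np.zeros((n, n))
    )


@pytest.fixture
def condition_high_pot():
    return PlasticitySignature(alpha_p=8.0, alpha_d=0.001, label="high pot")
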