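import numpy as np
import pytest

from thzneuro.model import (ConductanceModulation, HHParams, StimulusProtocol,
                            resting_state, simulate)

#: variant with a tonic-firing regime, used wherever sustained spiking is needed
TONIC_PARAMS = HHParams(k_gate_exponent=4, leak_gated=True)
TONIC_STIM = 10.0  # uA/cm^2, well above the tonic threshold (~2.7)


@pytest.fixture(scope="session")
def tonic_params():
    return TONIC_PARAMS


@pytest.fixture(scope="session")
def tonic_trace():
    """500 ms tonic-firing trace of the n^4 gated-leak variant (with gating)."""
    return simulate(TONIC_PARAMS, ConductanceModulation(),
                    StimulusProtocol.constant(TONIC_STIM, 500.0), 500.0, 0.01,
                    record_gating=True)


@pytest.fixture(scope="session")
def rest_trace():
    """200 ms stimulus-free run of the default model, started at rest."""
    p = HHParams()
    return simulate(p, ConductanceModulation(), StimulusProtocol.none(),
                    200.0, 0.01)


@pytest.fixture(scope="session")
def default_rest():
    return resting_state(HHParams())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
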