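import numpy as np
import pytest

from slicephys.synthetic import CCGroundTruth, synth_current_clamp
from slicephys.traceio import Trace, VOLTAGE_CLAMP


@pytest.fixture(scope="session")
def default_cc_recording():
    """One default neuron (CON pattern, ADP profile) with the standard
    sweep set; shared across feature-extraction tests."""
    return synth_current_clamp(CCGroundTruth(), seed=1)


@pytest.fixture(scope="session")
def noiseless_cc_recording():
    return synth_current_clamp(CCGroundTruth(), seed=1, noise_sd_mv=0.0)


@pytest.fixture()
def gauss_trace():
    rng = np.random.default_rng(7)
    return Trace(rng.normal(0.0, 2.0, 30_000), 10_000.0, VOLTAGE_CLAMP)
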