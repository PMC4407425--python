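import numpy as np
import pytest

from odisleep import SpO2Trace
from odisleep.synthetic import OximeterModel


def make_trace(values, valid=None, pulse=None) -> SpO2Trace:
    """Build a trace from a plain list of saturation values."""
    return SpO2Trace(spo2=np.asarray(values, dtype=float), pulse=pulse, valid=valid)


@pytest.fixture
def quiet_model() -> OximeterModel:
    """Oximeter with no noise and no artifacts: the clean instrument."""
    return OximeterModel(noise_sd=0.0, artifact_spike_rate=0.0, dropout_rate=0.0)


@pytest.fixture
def flat_trace() -> SpO2Trace:
    """Ten minutes of constant 96 % saturation."""
    return make_trace(np.full(600, 96.0))
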