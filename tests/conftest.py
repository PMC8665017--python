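import numpy as np
import pytest
from hypothesis import settings

from fecomap import preprocessing as pre
from fecomap import synthetic_data as syn

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def model() -> syn.GcampModel:
    return syn.GcampModel()


@pytest.fixture
def six_pulse_protocol() -> syn.StimulusProtocol:
    """The standard escalating six-pulse mapping protocol (first onset at 0)."""
    return syn.gen_stimulus_protocol()


def make_dff(values, dt=0.4, t0=0.0, label="roi") -> pre.DffTrace:
    """A DffTrace directly from ΔF/F values on a regular frame grid."""
    values = np.asarray(values, dtype=float)
    return pre.DffTrace(
        values=values,
        times=t0 + np.arange(len(values)) * dt,
        baseline_value=1.0,
        baseline_mode="synthetic",
        label=label,
    )


@pytest.fixture
def dff_factory():
    return make_dff
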