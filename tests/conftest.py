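import numpy as np
import pytest

from kinfp.idealize import IdealizedTrace
from kinfp.simulate import EmissionModel, TargetKinetics


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_emission():
    """Low-noise emission used where the test targets geometry, not noise."""
    return EmissionModel(mean_bound=1.0, mean_unbound=0.0, noise_sd=0.05)


def make_ideal(states, frame_time=0.1, mean_bound=1.0, mean_unbound=0.0,
               noise_sd=0.2, **kw):
    """IdealizedTrace from an explicit boolean state path (dwells derived)."""
    from kinfp.idealize import _dwells_from_states

    states = np.asarray(states, dtype=bool)
    d_on, d_off, cf, cl = _dwells_from_states(states, frame_time)
    return IdealizedTrace(
        states=states, mean_bound=mean_bound, mean_unbound=mean_unbound,
        noise_sd=noise_sd, dwells_on=d_on, dwells_off=d_off,
        censored_first=cf, censored_last=cl, frame_time=frame_time, **kw,
    )


@pytest.fixture
def miR16():
    return TargetKinetics("miR-16", 2.29, 2.69)
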