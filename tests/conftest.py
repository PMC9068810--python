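import numpy as np
import pytest

from hfqcompete import AcquisitionParams, BoundInterval, CompetitionParams
from hfqcompete.traces import IntensityTrace


@pytest.fixture
def quiet_acq():
    """Noise-free default acquisition (3,000 frames at 100 ms)."""
    return AcquisitionParams(noise_sd=0.0)


@pytest.fixture
def idle_params():
    """No arrivals, no passive dissociation: resident bound forever."""
    return CompetitionParams(k_arrival=0.0, k_passive=0.0)


def make_trace(values, channel="cy5", excited=None, frame_interval=0.1, molecule_id="m0"):
    values = np.asarray(values, dtype=float)
    if excited is None:
        excited = np.ones(values.size, dtype=bool)
    return IntensityTrace(molecule_id, channel, values, excited, frame_interval)


def interval(channel, t0, t1, stoich=1, left=False, right=False, segments=None):
    return BoundInterval(
        channel=channel,
        t_start=t0,
        t_end=t1,
        stoichiometry=stoich,
        left_censored=left,
        right_censored=right,
        segments=segments,
    )
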