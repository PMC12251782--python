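import numpy as np
import pytest

from enosekit.preprocess import FilterConfig, preprocess_recording, windowize
from enosekit.simulate import default_array, gen_intermittent, simulate_response


@pytest.fixture(scope="session")
def small_recording():
    """A 3-cycle intermittent recording with drift, shared across tests."""
    profile = gen_intermittent(3, seed=11)
    return simulate_response(profile, default_array(), seed=12, drift_on=True)


@pytest.fixture(scope="session")
def cycle_windows(small_recording):
    rec = preprocess_recording(small_recording, FilterConfig())
    return windowize(rec, 600, 600, recording_id="fixture")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
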