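import numpy as np
import pytest

from hrvb import pacing, simulate
from hrvb.signals import RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_rr():
    """10 intervals of exactly 1000 ms."""
    return RRSeries.from_intervals(np.full(10, 1000.0))


def make_stepped_session(profile, protocol=None):
    """Simulate a stepped session and slice it into per-frequency segments."""
    protocol = protocol or pacing.build_stepped_protocol()
    sess = simulate.simulate_session(profile, protocol)
    t0 = sess.rr.beat_times[0]
    out = []
    for k, freq in enumerate(protocol.frequencies):
        a = t0 + k * protocol.step_duration
        out.append((freq, sess.rr.slice_time(a, a + protocol.step_duration)))
    return sess, out


@pytest.fixture
def stepped_session_factory():
    return make_stepped_session
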