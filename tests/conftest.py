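import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Reduced envelope sampling rate for scheduling-only work: the scheduler
# reads the envelope on a 1 ms grid, so its statistics are unchanged while
# synthesis cost drops ~25x.  Stimulus-content tests use the full rate.
SCHED_RATE = 1000.0


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A small scheduled session (both orders of magnitude faster than the
    full 96-trial default but structurally identical)."""
    from avcoherence.scheduler import build_session

    return build_session(
        "pitch", np.random.default_rng(777), n_per_condition=4,
        envelope_rate=SCHED_RATE,
    )
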