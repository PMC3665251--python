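import numpy as np
import pytest

from mnhrf.design import DesignSet, EventSchedule
from mnhrf.simulate import build_schedule, canonical_hrf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def schedule():
    """Rapid schedule: 20 trials every 4 s (2 volumes at TR 2 s), blanks
    after every 5."""
    return build_schedule(20, tr=2.0, soa=4.0, blank_every=5,
                          rng=np.random.default_rng(7))


@pytest.fixture
def design(schedule):
    return DesignSet.from_schedule(schedule, hrf_length_samples=13)


@pytest.fixture
def hrf():
    return canonical_hrf(2.0, 13)


def random_schedule(rng, n_volumes=None, n_trials=None, tr=2.0):
    """Arbitrary valid schedule on the volume grid for property tests."""
    if n_volumes is None:
        n_volumes = int(rng.integers(30, 80))
    if n_trials is None:
        n_trials = int(rng.integers(1, max(2, n_volumes // 3)))
    vols = np.sort(rng.choice(n_volumes - 1, size=n_trials, replace=False))
    return EventSchedule(
        onsets=vols * tr,
        durations=np.full(n_trials, tr),
        labels=np.zeros(n_trials, dtype=int),
        run_length=n_volumes,
        tr=tr,
    )
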