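import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gazedecode.io_core import SessionConfig
from gazedecode.microsaccades import detect_microsaccades
from gazedecode.preprocess import preprocess_pupil
from gazedecode.synth import ObserverParams, make_schedule, simulate_session

#: default coupled observer used across pipeline tests: positive coupling on
#: every feature (rates in events/s, pupil offsets in a.u.)
COUPLING = np.array([0.6, 0.6, 0.6, 15.0, 15.0, 15.0])


def match_planted(planted, detected, tol_ms=10.0):
    """Greedy onset matching of planted vs detected events within +/-tol."""
    det_on = np.array([d.onset_ms for d in detected])
    used: set[int] = set()
    tp = 0
    for p in planted:
        js = [j for j in np.flatnonzero(np.abs(det_on - p.onset_ms) <= tol_ms) if j not in used]
        if js:
            used.add(js[0])
            tp += 1
    return tp


@pytest.fixture(scope="session")
def short_schedule():
    # 20-trial block: nearest-integer rounding gives 13 + 3 + 4 = 20
    return make_schedule(n_blocks=1, trials_per_block=20, seed=0)


@pytest.fixture(scope="session")
def coupled_session(short_schedule):
    obs = ObserverParams(coupling=COUPLING)
    return simulate_session(short_schedule, obs, seed=1)


@pytest.fixture(scope="session")
def preprocessed(coupled_session, short_schedule):
    return preprocess_pupil(coupled_session.recording, short_schedule)


@pytest.fixture(scope="session")
def detection(coupled_session, preprocessed):
    _, blinks = preprocessed
    return detect_microsaccades(coupled_session.recording, blinks, seed=0)
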