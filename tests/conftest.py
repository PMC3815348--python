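import numpy as np
import pytest

from fatiguemap import (
    EventSchedule,
    HRFParams,
    build_rating_series,
    generate_schedule,
)
from fatiguemap.paradigm import RATING_SCALES


@pytest.fixture(scope="session")
def schedule_6x32():
    """The standard six-run, 32-trial schedule."""
    return generate_schedule(n_runs=6, trials_per_run=32, seed=1)


@pytest.fixture(scope="session")
def small_schedule():
    """Two runs of four trials: cheap designs for GLM unit tests."""
    return generate_schedule(n_runs=2, trials_per_run=4, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant_ratings(value, scale="fatigue", n_boundaries=7):
    return build_rating_series([value] * n_boundaries, scale=scale,
                               n_boundaries=n_boundaries)


@pytest.fixture
def flat_rating_set():
    """All six scales constant at 50: amplitudes 0.5 everywhere."""
    return {s: constant_ratings(50.0, scale=s) for s in RATING_SCALES}


def single_event_schedule(onset_s, n_runs=1):
    """One trial per run at a chosen onset (for interpolation fractions)."""
    import pandas as pd

    rows = []
    for run in range(1, n_runs + 1):
        rows.append(dict(run=run, trial=1, onset_s=onset_s, cue="color",
                         task="color-judgment", cti_s=2.0, cue_s=0.5,
                         stimulus_s=1.0, trial_s=8.0))
    return EventSchedule(events=pd.DataFrame(rows))
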