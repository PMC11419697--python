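import numpy as np
import pytest

import altmaze as am
from altmaze import cohort, mazes


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-phase cohort (fast, deterministic) for pipeline tests."""
    cfg = cohort.CohortConfig(
        n_nonswitching=4,
        n_switching=4,
        phase1_days=3,
        phase2_days=3,
        trials_per_session=30,
        late_start_session=3,
        seed=7,
    )
    return cohort.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["plus", "H", "2T"])
def maze(request):
    return mazes.MAZES[request.param]


def perfect_plus_log(n_trials=20, seed=0, **meta):
    """A plus-maze log of an agent that never lapses."""
    strategy = am.LapseStrategy("location_bias", location_weights=(2, 1, 1, 0), p_lapse=0.0)
    return cohort.run_lapse_agent("plus", 0.0, strategy, n_trials, seed, meta=meta)
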