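import numpy as np
import pandas as pd
import pytest

from matchload import (
    GameObservation,
    GoalDiffTimeline,
    PlayerParameters,
    PlayerStint,
    build_gd_timeline,
)


@pytest.fixture
def flat_timeline():
    """90-minute game that stays 0-0."""
    return build_gd_timeline([], 90.0)


@pytest.fixture
def full_stint():
    return PlayerStint("p1", "g1", 0.0, 90.0)


@pytest.fixture
def constant_params():
    """All ten powers 600 J/kg/min, no endurance decay."""
    return PlayerParameters(powers=np.full((2, 5), 600.0), eta90=1.0)


def make_intervals(stint, energies, width=5.0, gd=0, expectation="f"):
    """Gap-free labelled-interval table covering the stint from entry."""
    starts = stint.t_s + width * np.arange(len(energies))
    df = pd.DataFrame(
        {
            "start_min": starts,
            "end_min": starts + width,
            "energy_jkg": energies,
            "gd": gd,
            "tau_start": starts - stint.t_s,
            "expectation": expectation,
        }
    )
    return df


def make_observation(
    timeline, stint, expectation, energies=None, intervals=None
):
    if intervals is None:
        intervals = make_intervals(stint, energies, expectation=expectation)
        # label gd from the timeline so observations are self-consistent
        intervals["gd"] = np.asarray(
            timeline.value_at(intervals["start_min"].to_numpy(float))
        )
    return GameObservation(
        player_id=stint.player_id,
        game_id=stint.game_id,
        timeline=timeline,
        stint=stint,
        expectation=expectation,
        intervals=intervals,
    )
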