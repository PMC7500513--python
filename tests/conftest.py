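import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from percross import (
    ClickEvent,
    ObjectKind,
    PASResponse,
    SessionDataset,
    TeamRecord,
    TrialRecord,
    WorldConfig,
)


@pytest.fixture
def world():
    return WorldConfig()


def make_trial(team_id, trial_number, clicks=(), pas=()):
    return TrialRecord(
        team_id=team_id,
        trial_number=trial_number,
        clicks=list(clicks),
        pas=list(pas),
    )


def click(player, time, position=100.0, target=None):
    return ClickEvent(player=player, time=time, position=position, target=target)


@pytest.fixture
def small_session():
    """2 teams x 3 trials, 5 clicks, hand-built."""
    t11 = make_trial(
        1,
        1,
        clicks=[
            click(1, 10.0, target=ObjectKind.OTHER_AVATAR),
            click(2, 12.9, target=ObjectKind.OTHER_AVATAR),
        ],
        pas=[PASResponse(1, 4), PASResponse(2, 3)],
    )
    t12 = make_trial(1, 2, clicks=[click(1, 30.0, target=ObjectKind.SHADOW)], pas=[PASResponse(1, 2)])
    t13 = make_trial(1, 3)
    t21 = make_trial(
        2,
        1,
        clicks=[
            click(1, 5.0, target=ObjectKind.OTHER_AVATAR),
            click(2, 25.0, target=ObjectKind.STATIC),
        ],
        pas=[PASResponse(2, 1)],
    )
    t22 = make_trial(2, 2)
    t23 = make_trial(2, 3)
    return SessionDataset(
        teams=[TeamRecord(1, [t11, t12, t13]), TeamRecord(2, [t21, t22, t23])]
    ).validate()


def random_session(rng, n_teams=2, n_trials=3):
    """Small random but valid event-level dataset for round-trip properties."""
    teams = []
    for j in range(n_teams):
        trials = []
        for t in range(1, n_trials + 1):
            clicks, pas = [], []
            for player in (1, 2):
                if rng.uniform() < 0.7:
                    clicks.append(
                        ClickEvent(
                            player=player,
                            time=round(float(rng.uniform(0, 60)), 3),
                            position=round(float(rng.uniform(0, 600)), 4),
                            target=ObjectKind(
                                rng.choice(["other_avatar", "shadow", "static", "unknown"])
                            ),
                        )
                    )
                    if rng.uniform() < 0.9:
                        pas.append(PASResponse(player=player, value=int(rng.integers(1, 5))))
            trials.append(
                TrialRecord(team_id=j + 1, trial_number=t, clicks=clicks, pas=pas)
            )
        teams.append(TeamRecord(team_id=j + 1, trials=trials))
    return SessionDataset(teams=teams).validate()
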