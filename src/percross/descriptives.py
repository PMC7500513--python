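"""Count tables, PAS cross-tabulations, and inter-click-interval analysis.

A trial's behavioural outcome is summarised per player (clicked? correct?
PAS) and per team (joint success, inter-click interval).  "Correct" means
the click was assigned to the partner's avatar; clicks at the shadow or the
static object count as incorrect.  The inter-click delay of a trial in which
both players clicked is dichotomized at a window (3 s by default, strict
inequality): this is the synchrony indicator used throughout the model.

The analytic null for the interval distribution treats both players' click
times as independent Uniform(0, T): the delay D = |X - Y| then has CDF
P(D < d) = 1 - ((T - d)/T)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .environment import ObjectKind
from .trial_data import SessionDataset

__all__ = [
    "TrialOutcome",
    "CountSummary",
    "trial_outcomes",
    "count_summary",
    "pas_crosstab",
    "null_interval_cdf",
    "interval_density",
    "team_score",
]

PAS_CONDITIONS = ("all", "incorrect", "correct_nonjoint", "correct_joint")


@dataclass
class TrialOutcome:
    """Outcome of one trial: per-player success/PAS and team-level synchrony."""

    team_id: int
    trial_number: int
    clicked: tuple[bool, bool]
    correct: tuple[bool | None, bool | None]  # None when the player did not click
    pas: tuple[int | None, int | None]
    joint_success: bool
    interclick_interval: float | None
    delay_indicator: int

    def player_rows(self):
        for p in (0, 1):
            yield {
                "team_id": self.team_id,
                "trial_number": self.trial_number,
                "player": p + 1,
                "clicked": self.clicked[p],
                "correct": self.correct[p],
                "pas": self.pas[p],
                "joint_success": self.joint_success,
                "delay_indicator": self.delay_indicator,
            }


@dataclass
class CountSummary:
    n_trials: int
    n_possible_clicks: int
    n_clicks: int
    n_correct: int
    n_joint_trials: int
    n_bothclick_nonjoint_trials: int
    n_pas: int
    pas_frequencies: dict[str, tuple[int, int, int, int]]

    @property
    def click_rate(self) -> float:
        return self.n_clicks / self.n_possible_clicks

    @property
    def correct_rate(self) -> float:
        return self.n_correct / self.n_clicks

    @property
    def joint_rate(self) -> float:
        return self.n_joint_trials / self.n_trials

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_possible_clicks": self.n_possible_clicks,
            "n_clicks": self.n_clicks,
            "n_correct": self.n_correct,
            "n_joint_trials": self.n_joint_trials,
            "n_bothclick_nonjoint_trials": self.n_bothclick_nonjoint_trials,
            "n_pas": self.n_pas,
            "click_rate": self.click_rate,
            "correct_rate": self.correct_rate,
            "joint_rate": self.joint_rate,
            "pas_frequencies": {k: list(v) for k, v in self.pas_frequencies.items()},
        }


def trial_outcomes(dataset: SessionDataset, delay_window: float = 3.0) -> list[TrialOutcome]:
    """One :class:`TrialOutcome` per recorded trial.

    Requires every click to carry a target (run click classification first).
    The delay indicator is 1 iff both players clicked and their interval is
    strictly below ``delay_window``; trials with fewer than two clicks have
    no interval and indicator 0.
    """
    out = []
    for team in dataset.teams:
        for trial in team.trials:
            clicked = [False, False]
            correct: list[bool | None] = [None, None]
            pas: list[int | None] = [None, None]
            times: list[float | None] = [None, None]
            for c in trial.clicks:
                if c.target is None:
                    raise ValueError(
                        f"team {team.team_id} trial {trial.trial_number}: click has no "
                        "target; run click_classification.classify_session first"
                    )
                p = c.player - 1
                clicked[p] = True
                correct[p] = c.target == ObjectKind.OTHER_AVATAR
                times[p] = c.time
            for r in trial.pas:
                pas[r.player - 1] = r.value
            if all(clicked):
                interval = abs(times[0] - times[1])
                indicator = int(interval < delay_window)
            else:
                interval, indicator = None, 0
            joint = bool(all(clicked) and correct[0] and correct[1])
            out.append(
                TrialOutcome(
                    team_id=team.team_id,
                    trial_number=trial.trial_number,
                    clicked=tuple(clicked),
                    correct=tuple(correct),
                    pas=tuple(pas),
                    joint_success=joint,
                    interclick_interval=interval,
                    delay_indicator=indicator,
                )
            )
    return out


def _pas_condition_mask(o: TrialOutcome, p: int, condition: str) -> bool:
    if not o.clicked[p] or o.pas[p] is None:
        return False
    if condition == "all":
        return True
    if condition == "incorrect":
        return not o.correct[p]
    if condition == "correct_nonjoint":
        return bool(o.correct[p]) and not o.joint_success
    if condition == "correct_joint":
        return bool(o.correct[p]) and o.joint_success
    raise ValueError(f"unknown PAS condition {condition!r}; use one of {PAS_CONDITIONS}")


def pas_crosstab(outcomes: list[TrialOutcome], condition: str = "all") -> np.ndarray:
    """Counts of PAS 1..4 among clicks meeting ``condition`` with a PAS response."""
    if condition not in PAS_CONDITIONS:
        raise ValueError(f"unknown PAS condition {condition!r}; use one of {PAS_CONDITIONS}")
    counts = np.zeros(4, dtype=int)
    for o in outcomes:
        for p in (0, 1):
            if _pas_condition_mask(o, p, condition):
                counts[o.pas[p] - 1] += 1
    return counts


def count_summary(outcomes: list[TrialOutcome]) -> CountSummary:
    """All headline counts; percentages are derived properties, never stored."""
    if not outcomes:
        raise ValueError("no trial outcomes to summarize")
    n_trials = len(outcomes)
    n_clicks = sum(sum(o.clicked) for o in outcomes)
    n_correct = sum(sum(bool(c) for c in o.correct if c is not None) for o in outcomes)
    n_joint = sum(o.joint_success for o in outcomes)
    n_both_nonjoint = sum(all(o.clicked) and not o.joint_success for o in outcomes)
    n_pas = sum(sum(v is not None for v in o.pas) for o in outcomes)
    freqs = {
        cond: tuple(int(x) for x in pas_crosstab(outcomes, cond)) for cond in PAS_CONDITIONS
    }
    return CountSummary(
        n_trials=n_trials,
        n_possible_clicks=2 * n_trials,
        n_clicks=n_clicks,
        n_correct=n_correct,
        n_joint_trials=n_joint,
        n_bothclick_nonjoint_trials=n_both_nonjoint,
        n_pas=n_pas,
        pas_frequencies=freqs,
    )


def null_interval_cdf(d: float, T: float = 60.0) -> float:
    """P(|X - Y| < d) for independent X, Y ~ Uniform(0, T)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > T):
        raise ValueError(f"delay must lie in [0, {T}]")
    out = 1.0 - ((T - d) / T) ** 2
    return float(out) if np.ndim(out) == 0 else out


def interval_density(
    intervals,
    T: float = 60.0,
    method: str = "reflect_kde",
    bandwidth: float | str | None = None,
    d: float = 3.0,
    grid_size: int = 2048,
) -> dict:
    """Boundary-corrected density of inter-click intervals on [0, T].

    The default estimator is a Gaussian KDE with mass reflected at both
    boundaries (Silverman bandwidth unless ``bandwidth`` overrides it), so
    the estimate integrates to 1 on the support.  Returns a dict with the
    evaluation ``grid``, the ``density``, and ``p_below`` = P(interval < d)
    by trapezoidal integration.  Degenerate samples (all intervals equal)
    are handled as a point mass.
    """
    x = np.asarray([v for v in intervals if v is not None], dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 intervals to estimate a density, got {x.size}")
    if np.any((x < 0) | (x > T)):
        raise ValueError("intervals must lie in [0, T]")
    if method != "reflect_kde":
        raise ValueError(f"unknown density method {method!r}")
    grid = np.linspace(0.0, T, grid_size)
    if np.ptp(x) == 0:  # point mass: KDE is singular
        atom = x[0]
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - atom))] = 1.0 / (grid[1] - grid[0])
        p_below = float(atom < d)
        return {"grid": grid, "density": density, "p_below": p_below, "d": d}
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    density = kde(grid) + kde(-grid) + kde(2 * T - grid)
    mask = grid <= d
    p_below = float(np.trapezoid(density[mask], grid[mask]))
    return {"grid": grid, "density": density, "p_below": p_below, "d": d}


def team_score(outcomes: list[TrialOutcome]) -> dict[int, int]:
    """Game score per team: +1 per correct click, -1 per incorrect click."""
    scores: dict[int, int] = {}
    for o in outcomes:
        s = scores.setdefault(o.team_id, 0)
        for p in (0, 1):
            if o.correct[p] is True:
                s += 1
            elif o.correct[p] is False:
                s -= 1
        scores[o.team_id] = s
    return scores


def outcomes_frame(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    """Player-level long-format view of outcomes (two rows per trial)."""
    return pd.DataFrame([row for o in outcomes for row in o.player_rows()])
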