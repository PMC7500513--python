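"""Counts, PAS cross-tabs, interval analysis and the uniform null."""

import numpy as np
import pytest
from scipy import stats

from conftest import click, make_trial

from percross import (
    ObjectKind,
    PASResponse,
    SessionDataset,
    TeamRecord,
    count_summary,
    interval_density,
    null_interval_cdf,
    pas_crosstab,
    team_score,
    trial_outcomes,
)


def session_of(trials):
    teams = {}
    for tr in trials:
        teams.setdefault(tr.team_id, []).append(tr)
    return SessionDataset(
        teams=[TeamRecord(tid, trs) for tid, trs in sorted(teams.items())]
    ).validate()


AV, SH, ST = ObjectKind.OTHER_AVATAR, ObjectKind.SHADOW, ObjectKind.STATIC


class TestTrialOutcomes:
    def test_delay_strictly_below_window(self):
        tr1 = make_trial(1, 1, clicks=[click(1, 10.0, target=AV), click(2, 12.9, target=AV)])
        tr2 = make_trial(1, 2, clicks=[click(1, 10.0, target=AV), click(2, 13.0, target=AV)])
        o1, o2 = trial_outcomes(session_of([tr1, tr2]))
        assert o1.interclick_interval == pytest.approx(2.9)
        assert o1.delay_indicator == 1
        assert o2.interclick_interval == pytest.approx(3.0)
        assert o2.delay_indicator == 0

    def test_single_click_has_no_interval(self):
        tr = make_trial(1, 1, clicks=[click(1, 10.0, target=AV)])
        (o,) = trial_outcomes(session_of([tr]))
        assert o.interclick_interval is None
        assert o.delay_indicator == 0
        assert not o.joint_success

    def test_unassigned_target_raises(self):
        tr = make_trial(1, 1, clicks=[click(1, 10.0)])
        with pytest.raises(ValueError, match="classify_session"):
            trial_outcomes(session_of([tr]))

    def test_window_monotonicity(self):
        tr = make_trial(1, 1, clicks=[click(1, 10.0, target=AV), click(2, 14.0, target=AV)])
        for w1, w2 in [(2.0, 5.0), (4.0, 10.0)]:
            (o1,) = trial_outcomes(session_of([tr]), delay_window=w1)
            (o2,) = trial_outcomes(session_of([tr]), delay_window=w2)
            assert o2.delay_indicator >= o1.delay_indicator


class TestCountSummary:
    def fixture_trials(self):
        return [
            make_trial(
                1, 1,
                clicks=[click(1, 10.0, target=AV), click(2, 11.0, target=AV)],
                pas=[PASResponse(1, 4), PASResponse(2, 3)],
            ),
            make_trial(1, 2, clicks=[click(1, 20.0, target=SH)], pas=[PASResponse(1, 2)]),
            make_trial(1, 3),
        ]

    def test_hand_counts(self):
        cs = count_summary(trial_outcomes(session_of(self.fixture_trials())))
        assert cs.n_trials == 3
        assert cs.n_possible_clicks == 6
        assert cs.n_clicks == 3
        assert cs.n_correct == 2
        assert cs.n_joint_trials == 1
        assert cs.n_bothclick_nonjoint_trials == 0
        assert cs.n_pas == 3

    def test_permutation_invariance(self):
        trials = self.fixture_trials()
        a = count_summary(trial_outcomes(session_of(trials)))
        b = count_summary(trial_outcomes(session_of(list(reversed(trials)))))
        assert a == b

    def test_joint_plus_nonjoint_is_bothclick(self):
        trials = self.fixture_trials() + [
            make_trial(
                2, 1, clicks=[click(1, 5.0, target=AV), click(2, 50.0, target=ST)]
            )
        ]
        outcomes = trial_outcomes(session_of(trials))
        cs = count_summary(outcomes)
        n_both = sum(all(o.clicked) for o in outcomes)
        assert cs.n_joint_trials + cs.n_bothclick_nonjoint_trials == n_both


class TestPasCrosstab:
    def test_all_fours(self):
        trials = [
            make_trial(
                1, t,
                clicks=[click(1, 5.0, target=AV)],
                pas=[PASResponse(1, 4)],
            )
            for t in range(1, 4)
        ]
        counts = pas_crosstab(trial_outcomes(session_of(trials)), "all")
        assert list(counts) == [0, 0, 0, 3]

    def test_unknown_condition_raises(self):
        with pytest.raises(ValueError, match="condition"):
            pas_crosstab([], "bogus")

    def test_conditions_partition_all(self):
        rng = np.random.default_rng(5)
        from conftest import random_session

        ds = random_session(rng, n_teams=4, n_trials=6)
        outcomes = trial_outcomes(ds)
        total = pas_crosstab(outcomes, "all")
        parts = sum(
            pas_crosstab(outcomes, c) for c in ("incorrect", "correct_nonjoint", "correct_joint")
        )
        assert np.array_equal(total, parts)


class TestNullIntervalCdf:
    def test_endpoints(self):
        assert null_interval_cdf(0.0) == 0.0
        assert null_interval_cdf(60.0) == 1.0

    def test_closed_form_value(self):
        assert null_interval_cdf(3.0, 60.0) == pytest.approx(0.0975)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(123)
        x, y = rng.uniform(0, 60, (2, 10**6))
        mc = np.mean(np.abs(x - y) < 3.0)
        assert null_interval_cdf(3.0, 60.0) == pytest.approx(mc, abs=1e-3)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            null_interval_cdf(-1.0)
        with pytest.raises(ValueError):
            null_interval_cdf(61.0)

    def test_is_exact_cdf_of_uniform_pair_delays(self):
        # KS test of simulated |X-Y| against the closed form
        rng = np.random.default_rng(7)
        x, y = rng.uniform(0, 60, (2, 10**5))
        d = np.abs(x - y)
        res = stats.ks_1samp(d, lambda v: null_interval_cdf(v, 60.0))
        assert res.pvalue > 0.01


class TestIntervalDensity:
    def test_uniform_null_probability(self):
        rng = np.random.default_rng(11)
        x, y = rng.uniform(0, 60, (2, 10**4))
        out = interval_density(np.abs(x - y), T=60.0, d=3.0)
        assert out["p_below"] == pytest.approx(0.0975, abs=0.02)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        out = interval_density(rng.exponential(2.0, 400) % 60, T=60.0)
        total = np.trapezoid(out["density"], out["grid"])
        assert total == pytest.approx(1.0, abs=0.01)

    def test_degenerate_atom(self):
        out_lo = interval_density([5.0] * 10, T=60.0, d=6.0)
        out_hi = interval_density([5.0] * 10, T=60.0, d=4.0)
        assert out_lo["p_below"] == pytest.approx(1.0)
        assert out_hi["p_below"] == pytest.approx(0.0)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError, match="at least 5"):
            interval_density([1.0, 2.0], T=60.0)


class TestTeamScore:
    def test_plus_minus_scoring(self):
        trials = [
            make_trial(1, 1, clicks=[click(1, 5.0, target=AV), click(2, 6.0, target=AV)]),
            make_trial(1, 2, clicks=[click(1, 5.0, target=SH)]),
            make_trial(2, 1),
        ]
        scores = team_score(trial_outcomes(session_of(trials)))
        assert scores == {1: 1, 2: 0}

    def test_all_correct(self):
        trials = [
            make_trial(1, t, clicks=[click(1, 5.0, target=AV), click(2, 6.0, target=AV)])
            for t in range(1, 6)
        ]
        assert team_score(trial_outcomes(session_of(trials))) == {1: 10}
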