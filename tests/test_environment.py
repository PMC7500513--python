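"""Torus geometry, overlap detection, and the trial simulator."""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from percross.environment import (
    InvalidConfiguration,
    WorldConfig,
    WorldState,
    objects_overlap,
    recompute_sensors,
    shadow_position,
    simulate_trial,
    torus_distance,
)

L = 600.0
pos = st.floats(min_value=0.0, max_value=599.999, allow_nan=False)


class TestTorusDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [(10, 595, 15), (0, 300, 300), (100, 100, 0), (0, 599, 1), (0, 0, 0)],
    )
    def test_examples(self, x, y, expected):
        assert torus_distance(x, y, L) == pytest.approx(expected)

    def test_invalid_length(self):
        with pytest.raises(InvalidConfiguration):
            torus_distance(1, 2, 0)

    @given(pos, pos, pos)
    def test_is_a_metric_on_the_circle(self, x, y, z):
        dxy = torus_distance(x, y, L)
        assert dxy == pytest.approx(torus_distance(y, x, L))
        assert 0 <= dxy <= L / 2
        assert torus_distance(x, x, L) == 0
        assert dxy <= torus_distance(x, z, L) + torus_distance(z, y, L) + 1e-9


class TestShadowPosition:
    def test_default_offset(self):
        assert shadow_position(100.0) == pytest.approx(250.0)

    def test_wraps(self):
        assert shadow_position(500.0) == pytest.approx(50.0)

    def test_zero_offset_is_identity(self):
        cfg = WorldConfig(shadow_offset=0.0)
        assert shadow_position(123.4, cfg) == pytest.approx(123.4)

    def test_negative_offset_configurable(self):
        cfg = WorldConfig(shadow_offset=-150.0)
        assert shadow_position(100.0, cfg) == pytest.approx(550.0)


def _overlap_bruteforce(x1, x2, cfg):
    """Point-membership oracle on a fine grid of object 1's interval."""
    for f in np.linspace(0, cfg.object_length, 400, endpoint=False):
        p = (x1 + f) % cfg.space_length
        d = (p - x2) % cfg.space_length
        if d < cfg.object_length:
            return True
    return False


class TestObjectsOverlap:
    @pytest.mark.parametrize(
        "x1, x2, expected",
        [(0, 3, True), (0, 4, False), (598, 1, True), (596, 0, False), (1, 598, True)],
    )
    def test_examples(self, x1, x2, expected):
        assert objects_overlap(x1, x2) is expected

    @given(pos, pos)
    def test_matches_bruteforce_and_symmetry(self, x1, x2):
        cfg = WorldConfig()
        got = objects_overlap(x1, x2, cfg)
        assert got == objects_overlap(x2, x1, cfg)
        assert got == _overlap_bruteforce(x1, x2, cfg)

    @given(pos, pos, pos)
    def test_translation_invariance(self, x1, x2, c):
        cfg = WorldConfig()
        assert objects_overlap(x1, x2, cfg) == objects_overlap(
            (x1 + c) % L, (x2 + c) % L, cfg
        )


class TestWorldState:
    def test_sensor_feels_partner_avatar_shadow_and_own_static(self):
        cfg = WorldConfig()
        # player 1 at 0; partner avatar at 2 -> overlap
        s = WorldState(avatar=(0.0, 2.0), static=(300.0, 400.0), config=cfg)
        assert s.sensor(0) == 1
        # partner's shadow at 150+2: put avatar 1 at 151 -> overlap with shadow
        s = WorldState(avatar=(151.0, 0.0), static=(300.0, 400.0), config=cfg)
        assert s.sensor(0) == 1
        # own static at 301 while avatar at 300 -> overlap
        s = WorldState(avatar=(300.0, 100.0), static=(301.0, 450.0), config=cfg)
        assert s.sensor(0) == 1

    def test_own_shadow_not_felt(self):
        cfg = WorldConfig()
        # player 1 avatar at 0, its own shadow at 150: put nothing else near 0
        s = WorldState(avatar=(150.0 - 150.0, 500.0), static=(300.0, 400.0), config=cfg)
        # avatar 1 at 0; its own shadow is at 150, partner at 500 (shadow 50)
        assert s.sensor(0) == 0


class TestSimulateTrial:
    cfg = WorldConfig(trial_duration=5.0, tick=0.01)

    @staticmethod
    def static_controller(history, t):
        return 0.0

    def test_nonoverlapping_static_players_never_sense(self):
        rec = simulate_trial(
            self.cfg,
            self.static_controller,
            self.static_controller,
            seed=1,
            start_positions=(0.0, 300.0),
            static_positions=(100.0, 200.0),
        )
        assert not rec.sensors[0].any() and not rec.sensors[1].any()

    def test_determinism(self):
        def jitter(history, t):
            return 10.0 if int(t * 100) % 7 else -5.0

        r1 = simulate_trial(self.cfg, jitter, jitter, seed=42)
        r2 = simulate_trial(self.cfg, jitter, jitter, seed=42)
        assert r1 == r2
        assert np.array_equal(r1.sensors[0], r2.sensors[0])

    def test_sweep_sensor_matches_posthoc_replay(self):
        def sweeper(history, t):
            return 120.0

        rec = simulate_trial(
            self.cfg,
            sweeper,
            self.static_controller,
            seed=3,
            start_positions=(0.0, 300.0),
            static_positions=(450.0, 200.0),
        )
        s0, s1 = recompute_sensors(rec)
        assert np.array_equal(rec.sensors[0], s0)
        assert np.array_equal(rec.sensors[1], s1)
        assert rec.sensors[0].sum() > 0  # the sweep hits something

    def test_second_click_ignored_with_warning(self, caplog):
        def clicky(history, t):
            return (0.0, t in (1.0, 2.0))

        with caplog.at_level(logging.WARNING, logger="percross.environment"):
            rec = simulate_trial(
                self.cfg,
                clicky,
                self.static_controller,
                seed=0,
                start_positions=(0.0, 300.0),
                static_positions=(100.0, 200.0),
            )
        assert len(rec.clicks) == 1
        assert rec.clicks[0].time == pytest.approx(1.0)
        assert any("ignored" in r.message for r in caplog.records)
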