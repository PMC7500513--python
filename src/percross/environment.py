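"""Mechanics of the invisible 1D circular virtual space.

Two players are embodied as small objects ("avatars") on a circle of
circumference ``space_length``.  Each avatar drags an identical "shadow"
object at a fixed offset, and each player additionally has a static object
placed somewhere on the circle.  A player's only percept is a binary contact
sensor that is on while their avatar overlaps any of the three objects they
can feel: the partner's avatar, the partner's shadow, and their own static
object.  This module provides the modular-arithmetic primitives and a
scriptable trial simulator used by the synthetic-data generator and by the
click-classification tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WorldConfig",
    "ObjectKind",
    "WorldState",
    "torus_distance",
    "shadow_position",
    "objects_overlap",
    "simulate_trial",
    "Controller",
]


class InvalidConfiguration(ValueError):
    """Raised when a world configuration violates its invariants."""


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and timing of the virtual environment.

    Units are the experiment's spatial units (circumference 600) and seconds.
    The shadow offset is applied in the positive direction by default; the
    original implementation's direction is unknown, so the sign is
    configurable.
    """

    space_length: float = 600.0
    object_length: float = 4.0
    shadow_offset: float = 150.0
    trial_duration: float = 60.0
    tick: float = 0.01

    def __post_init__(self) -> None:
        if self.space_length <= 0:
            raise InvalidConfiguration("space_length must be positive")
        if not (0 < self.object_length < self.space_length):
            raise InvalidConfiguration("object_length must be in (0, space_length)")
        if not (-self.space_length < self.shadow_offset < self.space_length):
            raise InvalidConfiguration("shadow_offset must have magnitude < space_length")
        if self.trial_duration <= 0:
            raise InvalidConfiguration("trial_duration must be positive")
        if self.tick <= 0:
            raise InvalidConfiguration("tick must be positive")


class ObjectKind(str, Enum):
    """What a click can be aimed at.

    ``unknown`` is a classification outcome only; it never labels a simulated
    object.
    """

    OTHER_AVATAR = "other_avatar"
    SHADOW = "shadow"
    STATIC = "static"
    UNKNOWN = "unknown"


@dataclass
class WorldState:
    """Instantaneous positions (left edges) of every object plus sensors.

    ``avatar`` and ``static`` are indexed by player (0-based internally);
    shadows are derived.  ``sensor[p]`` is 1 iff player ``p``'s avatar
    overlaps at least one of the three objects that player can feel.
    """

    avatar: tuple[float, float]
    static: tuple[float, float]
    config: WorldConfig = field(default_factory=WorldConfig)

    @property
    def shadow(self) -> tuple[float, float]:
        return (
            shadow_position(self.avatar[0], self.config),
            shadow_position(self.avatar[1], self.config),
        )

    def felt_objects(self, player: int) -> dict[ObjectKind, float]:
        """Positions of the three objects ``player`` (0 or 1) can feel."""
        other = 1 - player
        return {
            ObjectKind.OTHER_AVATAR: self.avatar[other],
            ObjectKind.SHADOW: self.shadow[other],
            ObjectKind.STATIC: self.static[player],
        }

    def sensor(self, player: int) -> int:
        own = self.avatar[player]
        for pos in self.felt_objects(player).values():
            if objects_overlap(own, pos, self.config):
                return 1
        return 0


def torus_distance(x: float, y: float, L: float) -> float:
    """Shortest arc distance between two points on a circle of length ``L``.

    Result lies in ``[0, L/2]``.  Accepts scalars or numpy arrays.
    """
    if np.any(np.asarray(L) <= 0):
        raise InvalidConfiguration("circle length must be positive")
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    out = np.minimum(d, L - d)
    return float(out) if np.ndim(out) == 0 else out


def shadow_position(avatar: float, cfg: WorldConfig | None = None) -> float:
    """Position of the shadow attached to an avatar at ``avatar``."""
    cfg = cfg or WorldConfig()
    return float(np.mod(avatar + cfg.shadow_offset, cfg.space_length))


def objects_overlap(x1: float, x2: float, cfg: WorldConfig | None = None) -> bool:
    """Whether two objects anchored at ``x1`` and ``x2`` intersect.

    Objects are half-open intervals ``[x, x + object_length)`` on the torus,
    so two objects whose edges merely touch do not overlap.
    """
    cfg = cfg or WorldConfig()
    # Half-open intervals of equal length w intersect iff the circular gap
    # between anchors is < w in either direction.
    L, w = cfg.space_length, cfg.object_length
    d = (x2 - x1) % L
    return bool(d < w or (L - d) < w)


#: A controller maps (own sensor history, current time) -> velocity in
#: units/second, and may request a click by returning (velocity, True).
Controller = Callable[[Sequence[int], float], "float | tuple[float, bool]"]


def simulate_trial(
    cfg: WorldConfig,
    controller_a: Controller,
    controller_b: Controller,
    seed: int = 0,
    *,
    start_positions: tuple[float, float] | None = None,
    static_positions: tuple[float, float] | None = None,
    team_id: int = 1,
    trial_number: int = 1,
):
    """Run one trial with scripted players and return a :class:`TrialRecord`.

    Controllers are called once per tick with their own sensor history (a
    list of 0/1 ints, most recent last) and the current time; they return
    either a velocity (units/second) or ``(velocity, click)``.  Only the
    first click per player is kept: later clicks are dropped with a logged
    warning, matching the experimental rule that a player may signal only
    once per trial.  All randomness (start positions if unspecified) is
    fixed by ``seed``.
    """
    from .trial_data import ClickEvent, TrialRecord

    rng = np.random.default_rng(seed)
    L = cfg.space_length
    if start_positions is None:
        start_positions = tuple(rng.uniform(0, L, size=2))
    if static_positions is None:
        static_positions = tuple(rng.uniform(0, L, size=2))

    n_ticks = int(round(cfg.trial_duration / cfg.tick))
    pos = [float(start_positions[0]) % L, float(start_positions[1]) % L]
    static = (float(static_positions[0]) % L, float(static_positions[1]) % L)

    times = np.empty(n_ticks + 1)
    traj = np.empty((n_ticks + 1, 2))
    sensors: list[list[int]] = [[], []]
    clicks: list[ClickEvent | None] = [None, None]
    controllers = (controller_a, controller_b)

    for k in range(n_ticks + 1):
        t = k * cfg.tick
        times[k] = t
        traj[k] = pos
        state = WorldState(avatar=(pos[0], pos[1]), static=static, config=cfg)
        for p in range(2):
            sensors[p].append(state.sensor(p))
        if k == n_ticks:
            break
        new_pos = list(pos)
        for p in range(2):
            out = controllers[p](sensors[p], t)
            if isinstance(out, tuple):
                vel, wants_click = out
            else:
                vel, wants_click = out, False
            if wants_click:
                if clicks[p] is None:
                    clicks[p] = ClickEvent(
                        player=p + 1, time=round(t, 3), position=pos[p]
                    )
                else:
                    logger.warning(
                        "player %d clicked again at t=%.2f; ignored (one click per trial)",
                        p + 1,
                        t,
                    )
            new_pos[p] = (pos[p] + vel * cfg.tick) % L
        pos = new_pos

    return TrialRecord(
        team_id=team_id,
        trial_number=trial_number,
        clicks=[c for c in clicks if c is not None],
        pas=[],
        times=times,
        trajectories=traj,
        static_positions=static,
        sensors=(np.array(sensors[0]), np.array(sensors[1])),
        world=cfg,
    )


def recompute_sensors(record) -> tuple[np.ndarray, np.ndarray]:
    """Recompute both sensor streams from a record's stored trajectories.

    Used as an independent check that the incrementally computed sensors in
    :func:`simulate_trial` agree with a post-hoc replay.
    """
    cfg = record.world or WorldConfig()
    out = []
    for p in range(2):
        vals = np.empty(len(record.times), dtype=int)
        for k in range(len(record.times)):
            state = WorldState(
                avatar=(record.trajectories[k, 0], record.trajectories[k, 1]),
                static=record.static_positions,
                config=cfg,
            )
            vals[k] = state.sensor(p)
        out.append(vals)
    return out[0], out[1]
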