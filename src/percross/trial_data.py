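"""Canonical data model and file I/O for perceptual-crossing sessions.

A session is a set of teams (dyads), each with an ordered list of trials.
Every trial may carry full avatar trajectories (simulated or recorded) or be
*trajectory-free*, holding only the click/PAS events — event-level files are
sufficient for all counting and for the Bayesian model.

File formats
------------
``events.csv``
    One row per player per recorded trial, columns (exact, in order):
    ``team_id, trial_number, player, click_time_s, click_position, target, pas``.
    Empty string encodes absence (no click, unassigned target, missing PAS).
``trajectories.csv``
    Long format: ``team_id, trial_number, time_s, player, avatar_position``.
``statics.csv`` (optional sidecar)
    ``team_id, trial_number, player, static_position`` — the static objects'
    anchors, needed to classify clicks from trajectories.
``session.json``
    Nested mirror of the same content plus the world configuration; a JSON
    Schema document is shipped under ``docs/session.schema.json``.

Missing PAS is always encoded as absent, never as a sentinel: the model
treats it as missing at random.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import ObjectKind, WorldConfig

__all__ = [
    "ClickEvent",
    "PASResponse",
    "TrialRecord",
    "TeamRecord",
    "SessionDataset",
    "ValidationError",
    "read_session",
    "write_session",
]

EVENT_COLUMNS = [
    "team_id",
    "trial_number",
    "player",
    "click_time_s",
    "click_position",
    "target",
    "pas",
]
TRAJECTORY_COLUMNS = ["team_id", "trial_number", "time_s", "player", "avatar_position"]
STATIC_COLUMNS = ["team_id", "trial_number", "player", "static_position"]


class ValidationError(ValueError):
    """A dataset or file violates the schema or an invariant."""


@dataclass
class ClickEvent:
    """A single click: who, when, where, and (once classified) at what."""

    player: int
    time: float
    position: float
    target: ObjectKind | None = None

    def validate(self, world: WorldConfig, where: str = "") -> None:
        if self.player not in (1, 2):
            raise ValidationError(f"{where}: player must be 1 or 2, got {self.player}")
        if not (0 <= self.time <= world.trial_duration):
            raise ValidationError(
                f"{where}: click time {self.time} outside [0, {world.trial_duration}]"
            )
        if not (0 <= self.position < world.space_length):
            raise ValidationError(
                f"{where}: click position {self.position} outside [0, {world.space_length})"
            )


@dataclass
class PASResponse:
    """Perceptual Awareness Scale rating (1 = no experience .. 4 = clear)."""

    player: int
    value: int

    def validate(self, where: str = "") -> None:
        if self.player not in (1, 2):
            raise ValidationError(f"{where}: player must be 1 or 2, got {self.player}")
        if self.value not in (1, 2, 3, 4):
            raise ValidationError(f"{where}: PAS must be in 1..4, got {self.value}")


@dataclass
class TrialRecord:
    """One 60-s trial of a team: trajectories (optional), clicks, PAS."""

    team_id: int
    trial_number: int
    clicks: list[ClickEvent] = field(default_factory=list)
    pas: list[PASResponse] = field(default_factory=list)
    times: np.ndarray | None = None
    trajectories: np.ndarray | None = None  # shape (n, 2), columns = players
    static_positions: tuple[float, float] | None = None
    sensors: tuple[np.ndarray, np.ndarray] | None = None
    world: WorldConfig | None = None

    @property
    def trajectory_free(self) -> bool:
        return self.trajectories is None

    def click_of(self, player: int) -> ClickEvent | None:
        for c in self.clicks:
            if c.player == player:
                return c
        return None

    def pas_of(self, player: int) -> PASResponse | None:
        for p in self.pas:
            if p.player == player:
                return p
        return None

    def validate(self, world: WorldConfig) -> None:
        where = f"team {self.team_id} trial {self.trial_number}"
        seen: set[int] = set()
        for c in self.clicks:
            c.validate(world, where)
            if c.player in seen:
                raise ValidationError(f"{where}: duplicate click for player {c.player}")
            seen.add(c.player)
        pas_seen: set[int] = set()
        for p in self.pas:
            p.validate(where)
            if p.player in pas_seen:
                raise ValidationError(f"{where}: duplicate PAS for player {p.player}")
            pas_seen.add(p.player)
            if p.player not in seen:
                raise ValidationError(
                    f"{where}: PAS response for player {p.player} without a click"
                )
        if self.trajectories is not None:
            if self.times is None or len(self.times) != len(self.trajectories):
                raise ValidationError(f"{where}: trajectory times/positions mismatch")
            if np.any(self.trajectories < 0) or np.any(
                self.trajectories >= world.space_length
            ):
                raise ValidationError(f"{where}: trajectory positions outside world")

    def __eq__(self, other) -> bool:  # array-aware equality
        if not isinstance(other, TrialRecord):
            return NotImplemented
        if (
            self.team_id != other.team_id
            or self.trial_number != other.trial_number
            or sorted(self.clicks, key=lambda c: c.player)
            != sorted(other.clicks, key=lambda c: c.player)
            or sorted(self.pas, key=lambda p: p.player)
            != sorted(other.pas, key=lambda p: p.player)
            or self.static_positions != other.static_positions
        ):
            return False
        for a, b in ((self.times, other.times), (self.trajectories, other.trajectories)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


@dataclass
class TeamRecord:
    team_id: int
    trials: list[TrialRecord] = field(default_factory=list)

    def validate(self, world: WorldConfig) -> None:
        numbers = [t.trial_number for t in self.trials]
        if len(set(numbers)) != len(numbers):
            raise ValidationError(f"team {self.team_id}: duplicate trial numbers")
        for t in self.trials:
            if t.team_id != self.team_id:
                raise ValidationError(
                    f"team {self.team_id}: trial carries team_id {t.team_id}"
                )
            t.validate(world)


@dataclass
class SessionDataset:
    """All teams of one experimental session plus the world configuration.

    Unbalanced designs are supported: teams may have different numbers of
    recorded trials (in the original study two teams lost their final
    trials to recording errors).
    """

    teams: list[TeamRecord] = field(default_factory=list)
    world: WorldConfig = field(default_factory=WorldConfig)

    def validate(self) -> "SessionDataset":
        ids = [t.team_id for t in self.teams]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate team ids")
        for team in self.teams:
            team.validate(self.world)
        return self

    def all_trials(self) -> list[TrialRecord]:
        return [tr for team in self.teams for tr in team.trials]

    @property
    def n_trials(self) -> int:
        return len(self.all_trials())

    @property
    def n_clicks(self) -> int:
        return sum(len(tr.clicks) for tr in self.all_trials())


# ---------------------------------------------------------------------------
# serialization helpers

def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(float(x))
    return str(x)


def _events_frame(ds: SessionDataset) -> pd.DataFrame:
    rows = []
    for team in ds.teams:
        for tr in team.trials:
            for player in (1, 2):
                c = tr.click_of(player)
                p = tr.pas_of(player)
                rows.append(
                    {
                        "team_id": team.team_id,
                        "trial_number": tr.trial_number,
                        "player": player,
                        "click_time_s": _fmt(c.time if c else None),
                        "click_position": _fmt(c.position if c else None),
                        "target": c.target.value if c and c.target else "",
                        "pas": _fmt(p.value if p else None),
                    }
                )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _parse_events(df: pd.DataFrame, world: WorldConfig, source: str) -> SessionDataset:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing columns {missing}")
    teams: dict[int, dict[int, TrialRecord]] = {}
    for i, row in df.iterrows():
        where = f"{source}:row {i + 2}"  # header is line 1
        try:
            team_id = int(row["team_id"])
            trial_number = int(row["trial_number"])
            player = int(row["player"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{where}: non-integer id field ({exc})") from exc
        trial = teams.setdefault(team_id, {}).setdefault(
            trial_number, TrialRecord(team_id=team_id, trial_number=trial_number)
        )
        t_raw = _cell(row["click_time_s"])
        x_raw = _cell(row["click_position"])
        target_raw = _cell(row["target"])
        pas_raw = _cell(row["pas"])
        if (t_raw is None) != (x_raw is None):
            raise ValidationError(f"{where}: click time and position must co-occur")
        if t_raw is not None:
            target = ObjectKind(target_raw) if target_raw else None
            if trial.click_of(player) is not None:
                raise ValidationError(f"{where}: duplicate click for player {player}")
            trial.clicks.append(
                ClickEvent(
                    player=player,
                    time=float(t_raw),
                    position=float(x_raw),
                    target=target,
                )
            )
        elif target_raw:
            raise ValidationError(f"{where}: target without a click")
        if pas_raw is not None:
            trial.pas.append(PASResponse(player=player, value=int(float(pas_raw))))
    out = SessionDataset(
        teams=[
            TeamRecord(team_id=tid, trials=[trials[k] for k in sorted(trials)])
            for tid, trials in sorted(teams.items())
        ],
        world=world,
    )
    return out.validate()


def _cell(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    return s if s else None


def _world_to_dict(w: WorldConfig) -> dict:
    return {
        "space_length": w.space_length,
        "object_length": w.object_length,
        "shadow_offset": w.shadow_offset,
        "trial_duration": w.trial_duration,
        "tick": w.tick,
    }


def _session_json(ds: SessionDataset) -> dict:
    teams = []
    for team in ds.teams:
        trials = []
        for tr in team.trials:
            d = {
                "trial_number": tr.trial_number,
                "clicks": [
                    {
                        "player": c.player,
                        "time_s": c.time,
                        "position": c.position,
                        "target": c.target.value if c.target else None,
                    }
                    for c in sorted(tr.clicks, key=lambda c: c.player)
                ],
                "pas": [
                    {"player": p.player, "value": p.value}
                    for p in sorted(tr.pas, key=lambda p: p.player)
                ],
            }
            if tr.static_positions is not None:
                d["static_positions"] = list(tr.static_positions)
            if tr.trajectories is not None:
                d["times_s"] = tr.times.tolist()
                d["avatar_positions"] = tr.trajectories.tolist()
            trials.append(d)
        teams.append({"team_id": team.team_id, "trials": trials})
    return {"world": _world_to_dict(ds.world), "teams": teams}


def _session_from_json(doc: dict, source: str) -> SessionDataset:
    try:
        world = WorldConfig(**doc.get("world", {}))
    except TypeError as exc:
        raise ValidationError(f"{source}: bad world config ({exc})") from exc
    teams = []
    for tdoc in doc.get("teams", []):
        trials = []
        for rdoc in tdoc.get("trials", []):
            clicks = [
                ClickEvent(
                    player=c["player"],
                    time=c["time_s"],
                    position=c["position"],
                    target=ObjectKind(c["target"]) if c.get("target") else None,
                )
                for c in rdoc.get("clicks", [])
            ]
            pas = [PASResponse(player=p["player"], value=p["value"]) for p in rdoc.get("pas", [])]
            times = rdoc.get("times_s")
            traj = rdoc.get("avatar_positions")
            statics = rdoc.get("static_positions")
            trials.append(
                TrialRecord(
                    team_id=tdoc["team_id"],
                    trial_number=rdoc["trial_number"],
                    clicks=clicks,
                    pas=pas,
                    times=np.asarray(times, dtype=float) if times is not None else None,
                    trajectories=np.asarray(traj, dtype=float) if traj is not None else None,
                    static_positions=tuple(statics) if statics else None,
                    world=world,
                )
            )
        teams.append(TeamRecord(team_id=tdoc["team_id"], trials=trials))
    return SessionDataset(teams=teams, world=world).validate()


# ---------------------------------------------------------------------------
# public I/O

def write_session(dataset: SessionDataset, path: str | os.PathLike, format: str = "csv") -> None:
    """Write a session to ``path``.

    CSV format writes a directory holding ``events.csv`` and, when
    trajectories are present, ``trajectories.csv`` and ``statics.csv``.
    JSON writes a single ``session.json``-style file.  Output is
    deterministic: writing an unmodified dataset twice yields identical
    bytes.
    """
    dataset.validate()
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_session_json(dataset), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    path.mkdir(parents=True, exist_ok=True)
    _events_frame(dataset).to_csv(path / "events.csv", index=False)
    traj_rows = []
    static_rows = []
    for team in dataset.teams:
        for tr in team.trials:
            if tr.trajectories is not None:
                for player in (1, 2):
                    traj_rows.append(
                        pd.DataFrame(
                            {
                                "team_id": team.team_id,
                                "trial_number": tr.trial_number,
                                "time_s": tr.times,
                                "player": player,
                                "avatar_position": tr.trajectories[:, player - 1],
                            }
                        )
                    )
            if tr.static_positions is not None:
                for player in (1, 2):
                    static_rows.append(
                        {
                            "team_id": team.team_id,
                            "trial_number": tr.trial_number,
                            "player": player,
                            "static_position": tr.static_positions[player - 1],
                        }
                    )
    if traj_rows:
        pd.concat(traj_rows, ignore_index=True)[TRAJECTORY_COLUMNS].to_csv(
            path / "trajectories.csv", index=False
        )
    if static_rows:
        pd.DataFrame(static_rows, columns=STATIC_COLUMNS).to_csv(
            path / "statics.csv", index=False
        )


def read_session(
    path: str | os.PathLike, format: str = "csv", world: WorldConfig | None = None
) -> SessionDataset:
    """Read and validate a session from ``path`` (see :func:`write_session`).

    Malformed rows raise :class:`ValidationError` naming the file and row.
    An events file with no rows yields a dataset with zero teams.
    """
    path = Path(path)
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return _session_from_json(json.load(fh), str(path))
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    world = world or WorldConfig()
    events_path = path / "events.csv" if path.is_dir() else path
    df = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    ds = _parse_events(df, world, str(events_path))
    traj_path = events_path.parent / "trajectories.csv"
    statics_path = events_path.parent / "statics.csv"
    if traj_path.exists():
        tdf = pd.read_csv(traj_path)
        for (team_id, trial_number), grp in tdf.groupby(["team_id", "trial_number"]):
            trial = _find_trial(ds, int(team_id), int(trial_number), str(traj_path))
            p1 = grp[grp["player"] == 1].sort_values("time_s")
            p2 = grp[grp["player"] == 2].sort_values("time_s")
            if len(p1) != len(p2) or not np.array_equal(
                p1["time_s"].to_numpy(), p2["time_s"].to_numpy()
            ):
                raise ValidationError(
                    f"{traj_path}: players' time grids differ in team {team_id} trial {trial_number}"
                )
            trial.times = p1["time_s"].to_numpy(dtype=float)
            trial.trajectories = np.column_stack(
                [p1["avatar_position"].to_numpy(dtype=float), p2["avatar_position"].to_numpy(dtype=float)]
            )
            trial.world = world
    if statics_path.exists():
        sdf = pd.read_csv(statics_path)
        for (team_id, trial_number), grp in sdf.groupby(["team_id", "trial_number"]):
            trial = _find_trial(ds, int(team_id), int(trial_number), str(statics_path))
            pos = {int(r["player"]): float(r["static_position"]) for _, r in grp.iterrows()}
            trial.static_positions = (pos[1], pos[2])
    return ds.validate()


def _find_trial(ds: SessionDataset, team_id: int, trial_number: int, source: str) -> TrialRecord:
    for team in ds.teams:
        if team.team_id == team_id:
            for tr in team.trials:
                if tr.trial_number == trial_number:
                    return tr
    raise ValidationError(
        f"{source}: team {team_id} trial {trial_number} absent from events file"
    )


def convert_original_logs(path: str | os.PathLike) -> SessionDataset:
    """Converter stub for the original study's log dialect.

    The deposited supplementary dataset's exact column layout has not been
    inspected; once it is, this function should map it onto ``events.csv``
    semantics.  Until then it raises ``NotImplementedError``.
    """
    raise NotImplementedError(
        "original log dialect converter not implemented; export the data to "
        "the documented events.csv schema instead"
    )
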