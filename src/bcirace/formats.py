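"""Plain-text file formats: command-log CSV, race-log JSON, track JSON,
flat key=value parameter files, and agent-config JSON.

All machine-readable output keeps full double precision; readers validate
structure and report the offending line or key.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import dataclasses

from .game import (BciRaceError, Command, GameParameters, Track)
from .engine import (CommandEvent, FieldCrossing, RaceResult, SpeedState,
                     TraceEvent)
from .agents import AgentConfig

__all__ = [
    "FormatError",
    "read_command_log",
    "write_command_log",
    "write_race_log",
    "read_race_log",
    "write_track",
    "read_track",
    "read_parameters",
    "write_parameters",
    "read_agent_config",
    "write_agent_config",
]

_LOG_HEADER = ["time_s", "command"]


class FormatError(BciRaceError, ValueError):
    pass


def read_command_log(path) -> list[CommandEvent]:
    """Read a ``time_s,command`` CSV into a validated command log."""
    events: list[CommandEvent] = []
    prev = 0.0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _LOG_HEADER:
            raise FormatError(
                f"{path}: line 1: expected header 'time_s,command', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            try:
                t = float(row[0])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: bad time {row[0]!r}") from None
            try:
                cmd = Command(row[1].strip().lower())
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: unknown command {row[1]!r}") from None
            if t < 0:
                raise FormatError(f"{path}: line {lineno}: negative time {t}")
            if t < prev:
                raise FormatError(
                    f"{path}: line {lineno}: times must be non-decreasing "
                    f"({t} < {prev})")
            prev = t
            events.append(CommandEvent(time=t, command=cmd))
    return events


def write_command_log(log: Sequence[CommandEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LOG_HEADER)
        for ev in log:
            writer.writerow([repr(ev.time), ev.command.value])


def _result_to_json_obj(result: RaceResult) -> dict:
    return {
        "finish_time_s": result.finish_time,
        "events": [
            {"t": ev.time, "type": ev.type, "field_index": ev.field_index,
             "state": ev.state.value, "position": ev.position}
            for ev in result.events
        ],
        "per_field": [
            {"field_index": c.field_index, "entry_time": c.entry_time,
             "exit_time": c.exit_time,
             "commands": [{"time_s": e.time, "command": e.command.value}
                          for e in c.commands_received]}
            for c in result.per_field
        ],
    }


def write_race_log(result: RaceResult, path) -> None:
    """Write a race result as JSON with stable keys and full precision."""
    with open(path, "w") as fh:
        json.dump(_result_to_json_obj(result), fh, indent=1)
        fh.write("\n")


def read_race_log(path) -> RaceResult:
    with open(path) as fh:
        obj = json.load(fh)
    try:
        events = [
            TraceEvent(time=e["t"], type=e["type"],
                       field_index=e["field_index"],
                       state=SpeedState(e["state"]), position=e["position"])
            for e in obj["events"]
        ]
        per_field = [
            FieldCrossing(
                field_index=c["field_index"], entry_time=c["entry_time"],
                exit_time=c["exit_time"],
                commands_received=[
                    CommandEvent(time=e["time_s"], command=Command(e["command"]))
                    for e in c["commands"]])
            for c in obj["per_field"]
        ]
        return RaceResult(finish_time=obj["finish_time_s"], events=events,
                          per_field=per_field)
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed race log: {exc}") from exc


def write_track(track: Track, path) -> None:
    with open(path, "w") as fh:
        fh.write(track.to_json())
        fh.write("\n")


def read_track(path) -> Track:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    return Track.from_json_obj(obj)


def write_parameters(params: GameParameters, path) -> None:
    """Write a flat ``key=value`` parameter file (one key per line)."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(GameParameters):
            fh.write(f"{f.name}={getattr(params, f.name)!r}\n")


def read_parameters(path) -> GameParameters:
    values: dict[str, float] = {}
    names = {f.name for f in dataclasses.fields(GameParameters)}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in names:
                raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
            if key in values:
                raise FormatError(f"{path}: line {lineno}: duplicate key {key!r}")
            try:
                values[key] = float(value.strip())
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: bad value {value!r}") from None
    missing = sorted(names - set(values) - {"preview_horizon"})
    if missing:
        raise FormatError(f"{path}: missing keys: {missing}")
    return GameParameters(**values)


def read_agent_config(path) -> AgentConfig:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    return AgentConfig.from_json_obj(obj)


def write_agent_config(config: AgentConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_json_obj(), fh, indent=1)
        fh.write("\n")
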