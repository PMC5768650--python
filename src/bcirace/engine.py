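"""Deterministic single-avatar race dynamics.

The avatar moves along the track at a piecewise-constant speed determined
by a (speed-state, field-kind) pair:

====================  ==================  =====================
state                 no-input field      action field
====================  ==================  =====================
DEFAULT               s_default_noinput   s_default_action
REWARD                (unreachable)       s_reward_action
PENALTY               s_punish_noinput    s_punish_action
====================  ==================  =====================

Commands change the state: on an action field the correct command gives
REWARD and any other command gives PENALTY, each overriding the previous
effect and lasting to the end of the field; on a no-input field any
command gives PENALTY for at most ``t_max_punish_noinput`` seconds, and
every further command restarts that timer.  Crossing into a new field
always resets the state to DEFAULT and cancels a pending penalty timer.

Because the speed is piecewise constant, motion is integrated exactly by
an event-driven sweep over command arrivals, penalty expirations and
field-boundary crossings.  Tie-break at equal timestamps: boundary
crossing, then penalty expiration, then command — so a command arriving
exactly at a boundary is applied to the field being entered.

:func:`simulate_race_stepped` is a fixed-step integrator over the same
rules, kept as an independent cross-check of the event-driven engine.
"""

from __future__ import annotations

import bisect
import enum
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

from .game import (BciRaceError, Command, Field, FieldKind, GameParameters,
                   Track)

__all__ = [
    "EngineError",
    "SpeedState",
    "CommandEvent",
    "CommandLog",
    "TraceEvent",
    "FieldCrossing",
    "RaceResult",
    "RaceSimulator",
    "speed_of",
    "transition",
    "simulate_race",
    "simulate_race_stepped",
    "FIELD_ENTER",
    "COMMAND_APPLIED",
    "STATE_CHANGE",
    "PENALTY_EXPIRED",
    "FINISH",
]


class EngineError(BciRaceError, ValueError):
    pass


class SpeedState(enum.Enum):
    DEFAULT = "default"
    REWARD = "reward"
    PENALTY = "penalty"


@dataclass(frozen=True)
class CommandEvent:
    """One timestamped command, in seconds since race start."""

    time: float
    command: Command


CommandLog = Sequence[CommandEvent]

# Trace event types (stable strings, also used in the JSON race log).
FIELD_ENTER = "field_enter"
COMMAND_APPLIED = "command_applied"
STATE_CHANGE = "state_change"
PENALTY_EXPIRED = "penalty_expired"
FINISH = "finish"


@dataclass(frozen=True)
class TraceEvent:
    time: float
    type: str
    field_index: int
    state: SpeedState
    position: float


@dataclass
class FieldCrossing:
    field_index: int
    entry_time: float
    exit_time: float | None
    commands_received: list[CommandEvent] = dc_field(default_factory=list)


@dataclass
class RaceResult:
    """Finish time plus the full event trace for metric extraction."""

    finish_time: float
    events: list[TraceEvent]
    per_field: list[FieldCrossing]


def speed_of(state: SpeedState, kind: FieldKind, params: GameParameters) -> float:
    """Avatar speed for a reachable (state, field-kind) pair."""
    if state is SpeedState.DEFAULT:
        return params.s_default_noinput if kind is FieldKind.NO_INPUT else params.s_default_action
    if state is SpeedState.REWARD:
        if kind is FieldKind.NO_INPUT:
            raise EngineError("REWARD is unreachable on a NO_INPUT field")
        return params.s_reward_action
    return params.s_punish_noinput if kind is FieldKind.NO_INPUT else params.s_punish_action


def transition(state: SpeedState, cmd: Command, kind: FieldKind,
               params: GameParameters) -> tuple[SpeedState, float | None]:
    """State after a command, plus the penalty-timer duration if one starts.

    On a no-input field every command (re)starts the bounded penalty; on an
    action field the correct command yields REWARD and any other command
    yields an untimed PENALTY, either one overriding the current effect.
    Re-sending the active correct command is idempotent.
    """
    if kind is FieldKind.NO_INPUT:
        return SpeedState.PENALTY, params.t_max_punish_noinput
    if cmd is kind.correct_command:
        return SpeedState.REWARD, None
    return SpeedState.PENALTY, None


def _validate_log(log: CommandLog) -> None:
    prev = 0.0
    for i, ev in enumerate(log):
        if ev.time < 0:
            raise EngineError(f"command {i} has negative time {ev.time}")
        if ev.time < prev:
            raise EngineError(
                f"command log not time-sorted at index {i} "
                f"({ev.time} < {prev})")
        prev = ev.time


# tie-break priority at equal event times
_BOUNDARY, _EXPIRY, _COMMAND = 0, 1, 2


class RaceSimulator:
    """Incremental event-driven integrator over one track.

    State is anchored at the last processed event; between events the
    position is an affine function of time, so observations at arbitrary
    times never mutate the integrator.  This makes a closed-loop run and
    an open-loop replay of its emitted command log bit-identical.
    """

    def __init__(self, track: Track, params: GameParameters):
        self.track = track
        self.params = params
        self.t = 0.0
        self.pos = 0.0
        self.field_index = 0
        self.state = SpeedState.DEFAULT
        self.penalty_expiry: float | None = None
        self._pending: list[CommandEvent] = []
        self.finished = False
        self.finish_time: float | None = None
        self.events: list[TraceEvent] = [
            TraceEvent(0.0, FIELD_ENTER, 0, SpeedState.DEFAULT, 0.0)]
        self.per_field: list[FieldCrossing] = [FieldCrossing(0, 0.0, None)]

    @property
    def current_field(self) -> Field:
        return self.track.fields[self.field_index]

    @property
    def speed(self) -> float:
        return speed_of(self.state, self.current_field.kind, self.params)

    def position_at(self, t: float) -> float:
        """Position at a time in the current inter-event segment."""
        if t < self.t:
            raise EngineError(f"time {t} precedes current anchor {self.t}")
        return self.pos + self.speed * (t - self.t)

    def push_command(self, ev: CommandEvent) -> None:
        if ev.time < self.t:
            raise EngineError(
                f"command at {ev.time} is in the simulator's past (t={self.t})")
        bisect.insort_right(self._pending, ev, key=lambda e: e.time)

    def push_commands(self, log: CommandLog) -> None:
        _validate_log(log)
        for ev in log:
            self.push_command(ev)

    def _next_event(self) -> tuple[float, int]:
        t_boundary = self.t + (self.current_field.end_position - self.pos) / self.speed
        best = (t_boundary, _BOUNDARY)
        if self.penalty_expiry is not None:
            cand = (self.penalty_expiry, _EXPIRY)
            if cand < best:
                best = cand
        if self._pending:
            cand = (self._pending[0].time, _COMMAND)
            if cand < best:
                best = cand
        return best

    def peek_next_event_time(self) -> float:
        if self.finished:
            raise EngineError("race already finished")
        return self._next_event()[0]

    def step(self) -> TraceEvent:
        """Process the next event and return its primary trace record."""
        if self.finished:
            raise EngineError("race already finished")
        t_ev, tag = self._next_event()
        if tag == _BOUNDARY:
            self.t = t_ev
            self.pos = self.current_field.end_position
            self.per_field[-1].exit_time = t_ev
            if self.field_index == len(self.track.fields) - 1:
                self.finished = True
                self.finish_time = t_ev
                ev = TraceEvent(t_ev, FINISH, self.field_index, self.state, self.pos)
            else:
                self.field_index += 1
                self.state = SpeedState.DEFAULT
                self.penalty_expiry = None
                self.per_field.append(FieldCrossing(self.field_index, t_ev, None))
                ev = TraceEvent(t_ev, FIELD_ENTER, self.field_index,
                                SpeedState.DEFAULT, self.pos)
            self.events.append(ev)
            return ev
        if tag == _EXPIRY:
            self.pos = self.position_at(t_ev)
            self.t = t_ev
            self.state = SpeedState.DEFAULT
            self.penalty_expiry = None
            ev = TraceEvent(t_ev, PENALTY_EXPIRED, self.field_index,
                            SpeedState.DEFAULT, self.pos)
            self.events.append(ev)
            return ev
        cmd = self._pending.pop(0)
        self.pos = self.position_at(t_ev)
        self.t = t_ev
        old = self.state
        new_state, timer = transition(old, cmd.command,
                                      self.current_field.kind, self.params)
        self.state = new_state
        self.penalty_expiry = t_ev + timer if timer is not None else None
        self.per_field[-1].commands_received.append(cmd)
        ev = TraceEvent(t_ev, COMMAND_APPLIED, self.field_index, new_state, self.pos)
        self.events.append(ev)
        if new_state is not old:
            self.events.append(TraceEvent(t_ev, STATE_CHANGE, self.field_index,
                                          new_state, self.pos))
        return ev

    def run_to_finish(self) -> None:
        while not self.finished:
            self.step()

    def result(self) -> RaceResult:
        if not self.finished:
            raise EngineError("race has not finished")
        assert self.finish_time is not None
        return RaceResult(finish_time=self.finish_time, events=self.events,
                          per_field=self.per_field)


def simulate_race(track: Track, params: GameParameters,
                  log: CommandLog) -> RaceResult:
    """Replay a timestamped command log over a track; exact integration.

    Deterministic in its inputs.  Commands timestamped after the finish
    are ignored.
    """
    sim = RaceSimulator(track, params)
    sim.push_commands(log)
    sim.run_to_finish()
    return sim.result()


def simulate_race_stepped(track: Track, params: GameParameters,
                          log: CommandLog, dt: float) -> RaceResult:
    """Fixed-step integrator over the same rules (testing oracle).

    Marches a time grid of step ``dt``, splitting a step only where a
    command or a penalty expiration falls inside it, and caps motion at
    field boundaries within a step.  Converges to :func:`simulate_race`
    as ``dt`` shrinks; records a coarser trace (entries, commands,
    expirations, finish).
    """
    if dt <= 0:
        raise EngineError(f"dt must be positive, got {dt}")
    _validate_log(log)
    fields = track.fields
    t = 0.0
    pos = 0.0
    fi = 0
    state = SpeedState.DEFAULT
    expiry: float | None = None
    finish: float | None = None
    i, n = 0, len(log)
    per_field = [FieldCrossing(0, 0.0, None)]
    events = [TraceEvent(0.0, FIELD_ENTER, 0, SpeedState.DEFAULT, 0.0)]

    def advance_to(until: float) -> None:
        nonlocal t, pos, fi, state, expiry, finish
        while True:
            sp = speed_of(state, fields[fi].kind, params)
            t_cross = t + (fields[fi].end_position - pos) / sp
            if t_cross > until:
                pos += sp * (until - t)
                t = until
                return
            t = t_cross
            pos = fields[fi].end_position
            per_field[-1].exit_time = t
            if fi == len(fields) - 1:
                finish = t
                events.append(TraceEvent(t, FINISH, fi, state, pos))
                return
            fi += 1
            state = SpeedState.DEFAULT
            expiry = None
            per_field.append(FieldCrossing(fi, t, None))
            events.append(TraceEvent(t, FIELD_ENTER, fi, SpeedState.DEFAULT, pos))

    step_idx = 0
    while finish is None:
        step_idx += 1
        t_grid = step_idx * dt
        while finish is None:
            tc = log[i].time if i < n else math.inf
            te = expiry if expiry is not None else math.inf
            t_ev = min(tc, te)
            if t_ev > t_grid:
                break
            advance_to(t_ev)
            if finish is not None:
                break
            if te <= tc:
                if expiry is not None:  # a crossing at the same instant cancels it
                    state = SpeedState.DEFAULT
                    expiry = None
                    events.append(TraceEvent(t, PENALTY_EXPIRED, fi, state, pos))
            else:
                ev = log[i]
                i += 1
                state, timer = transition(state, ev.command, fields[fi].kind, params)
                expiry = t + timer if timer is not None else None
                per_field[-1].commands_received.append(ev)
                events.append(TraceEvent(t, COMMAND_APPLIED, fi, state, pos))
        if finish is None:
            advance_to(t_grid)

    return RaceResult(finish_time=finish, events=events, per_field=per_field)
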