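"""Closed-loop pilot models.

An agent observes the race at discrete decision times and may emit one
command per decision; the emission reaches the game ``latency`` seconds
later.  Four models are provided:

* ``silent`` — never sends a command (the guaranteed-finish baseline);
* ``spam`` — sends a uniformly random command at a fixed period;
* ``oracle`` — sends the correct command a fixed latency after entering
  each action field (an upper performance bound);
* ``classifier`` — a confusion-matrix model of an asynchronous BCI: at
  every decision tick the pilot *intends* either one command or rest, and
  the emitted output is sampled from the intent's row of a 4x4
  row-stochastic matrix whose fourth column is "no output".  False
  positives on no-input fields arise solely from the rest row.

The default intent policy intends the current action field's correct
command (after an optional entry delay, and only if that command is in
the pilot's command subset), rests otherwise, and stops intending once
the reward speed has been achieved on the current field.  Real pilots'
strategies varied and were not recorded; this policy is a modelling
choice, with ``entry_delay`` and ``command_subset`` as its tunable
surface.
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Sequence

import numpy as np

from .game import BciRaceError, Command, FieldKind, GameParameters, Track
from .engine import (FIELD_ENTER, CommandEvent, RaceResult, RaceSimulator,
                     SpeedState, speed_of)

__all__ = [
    "AgentError",
    "Observation",
    "ClassifierProfile",
    "AgentConfig",
    "Agent",
    "silent_agent",
    "spam_agent",
    "oracle_agent",
    "classifier_agent",
    "identity_profile",
    "profile_from_accuracy",
    "make_agent",
    "run_closed_loop",
    "INTENT_ORDER",
    "EMISSION_ORDER",
]


class AgentError(BciRaceError, ValueError):
    pass


#: Confusion-matrix row order: the three command intents, then rest.
INTENT_ORDER: tuple = (Command.ROTATE, Command.JUMP, Command.SLIDE, "rest")
#: Column order: the three emitted commands, then no output.
EMISSION_ORDER: tuple = (Command.ROTATE, Command.JUMP, Command.SLIDE, None)

_INTENT_INDEX = {intent: i for i, intent in enumerate(INTENT_ORDER)}
_REST = 3


@dataclass(frozen=True)
class Observation:
    """What a pilot can see at one decision time.

    ``upcoming_fields`` lists the kinds of the contiguous run of fields
    beyond the current one that are within the preview horizon — within
    ``preview_horizon`` seconds of travel at the current speed, or within
    ``preview_horizon`` seconds of default-pace travel (the rule that
    guarantees a silent avatar at least 10 s of preview).  Nothing beyond
    the horizon is revealed.
    """

    time: float
    field_index: int
    field_kind: FieldKind
    distance_to_field_end: float
    upcoming_fields: tuple[FieldKind, ...]
    state: SpeedState
    time_in_field: float


@dataclass(frozen=True)
class ClassifierProfile:
    """Timing and confusion structure of a simulated BCI pilot.

    ``confusion`` is row-stochastic with rows :data:`INTENT_ORDER` and
    columns :data:`EMISSION_ORDER`.  ``decision_period`` is the interval
    between classifier outputs, ``latency`` the delay from decision to
    the command reaching the game, and ``entry_delay`` a strategy
    parameter: how long to keep resting after entering an action field.
    """

    confusion: np.ndarray
    decision_period: float = 0.5
    latency: float = 0.0
    entry_delay: float = 0.0
    command_subset: frozenset = frozenset(Command)

    def __post_init__(self) -> None:
        m = np.asarray(self.confusion, dtype=float)
        if m.shape != (4, 4):
            raise AgentError(f"confusion matrix must be 4x4, got {m.shape}")
        if (m < 0).any():
            raise AgentError("confusion matrix entries must be non-negative")
        sums = m.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise AgentError(f"confusion rows must sum to 1, got {sums}")
        object.__setattr__(self, "confusion", m)
        object.__setattr__(self, "command_subset", frozenset(self.command_subset))
        if self.decision_period <= 0:
            raise AgentError("decision_period must be positive")
        if self.latency < 0 or self.entry_delay < 0:
            raise AgentError("latency and entry_delay must be non-negative")
        if not self.command_subset <= set(Command):
            raise AgentError("command_subset must contain only commands")

    def to_json_obj(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "decision_period": self.decision_period,
            "latency": self.latency,
            "entry_delay": self.entry_delay,
            "command_subset": sorted(c.value for c in self.command_subset),
        }

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "ClassifierProfile":
        kwargs = dict(obj)
        if "command_subset" in kwargs:
            kwargs["command_subset"] = frozenset(
                Command(c) for c in kwargs["command_subset"])
        return cls(**kwargs)


def identity_profile(**kwargs) -> ClassifierProfile:
    """A perfect pilot: every intent is emitted verbatim, rest emits nothing."""
    return ClassifierProfile(confusion=np.eye(4), **kwargs)


def profile_from_accuracy(accuracy: float, false_positive_rate: float = 0.0,
                          **kwargs) -> ClassifierProfile:
    """Profile with a scalar command accuracy.

    Each command intent is emitted correctly with probability ``accuracy``
    and as one of the two wrong commands with probability (1-accuracy)/2
    each (never as "no output").  The rest intent emits each command with
    probability ``false_positive_rate``/3 and nothing otherwise.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise AgentError(f"accuracy must lie in [0, 1], got {accuracy}")
    if not 0.0 <= false_positive_rate <= 1.0:
        raise AgentError(
            f"false_positive_rate must lie in [0, 1], got {false_positive_rate}")
    m = np.full((4, 4), 0.0)
    for r in range(3):
        m[r, :3] = (1.0 - accuracy) / 2.0
        m[r, r] = accuracy
    m[_REST, :3] = false_positive_rate / 3.0
    m[_REST, 3] = 1.0 - false_positive_rate
    return ClassifierProfile(confusion=m, **kwargs)


class Agent(abc.ABC):
    """Base pilot model; subclasses override the decision hooks they use."""

    #: seconds between periodic decision ticks; ``None`` disables ticks
    tick_period: float | None = None
    #: "global": ticks at multiples of the period from race start;
    #: "field_entry": the tick phase restarts at every field entry
    tick_phase: str = "global"
    #: delay from decision to the command reaching the game
    latency: float = 0.0
    #: whether the agent is woken at every field entry
    observes_field_entry: bool = False

    def reset(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def on_tick(self, obs: Observation) -> Command | None:
        return None

    def on_field_enter(self, obs: Observation) -> Command | None:
        return None


class SilentAgent(Agent):
    """Sends no commands; finishes at the guaranteed-finish baseline time."""


class SpamAgent(Agent):
    """Emits one uniformly random command at every multiple of the period."""

    def __init__(self, spam_period: float):
        if spam_period <= 0:
            raise AgentError(f"spam_period must be positive, got {spam_period}")
        self.tick_period = float(spam_period)

    def on_tick(self, obs: Observation) -> Command:
        return EMISSION_ORDER[self._rng.integers(3)]


class OracleAgent(Agent):
    """Sends the correct command a fixed latency after entering an action field."""

    observes_field_entry = True

    def __init__(self, latency: float = 0.0):
        if latency < 0:
            raise AgentError(f"latency must be non-negative, got {latency}")
        self.latency = float(latency)

    def on_field_enter(self, obs: Observation) -> Command | None:
        return obs.field_kind.correct_command


class ClassifierAgent(Agent):
    """Confusion-matrix pilot; see the module docstring for the intent policy.

    Decision ticks are phased to field entry (first tick on entering a
    field, then every ``decision_period``), reflecting the field-driven
    intent policy; a perfect profile therefore reproduces the zero-latency
    oracle exactly.
    """

    tick_phase = "field_entry"

    def __init__(self, profile: ClassifierProfile):
        self.profile = profile
        self.tick_period = profile.decision_period
        self.latency = profile.latency

    def reset(self, rng: np.random.Generator) -> None:
        super().reset(rng)
        self._cdf = np.cumsum(self.profile.confusion, axis=1)
        self._rewarded_field = -1

    def _intent(self, obs: Observation) -> int:
        kind = obs.field_kind
        if not kind.is_action:
            return _REST
        if obs.state is SpeedState.REWARD:
            self._rewarded_field = obs.field_index
        if self._rewarded_field == obs.field_index:
            return _REST
        if obs.time_in_field < self.profile.entry_delay:
            return _REST
        correct = kind.correct_command
        if correct not in self.profile.command_subset:
            return _REST
        return _INTENT_INDEX[correct]

    def on_tick(self, obs: Observation) -> Command | None:
        row = self._intent(obs)
        col = int(np.searchsorted(self._cdf[row], self._rng.random(), side="right"))
        return EMISSION_ORDER[min(col, 3)]


def silent_agent() -> SilentAgent:
    return SilentAgent()


def spam_agent(spam_period: float) -> SpamAgent:
    return SpamAgent(spam_period)


def oracle_agent(latency: float = 0.0) -> OracleAgent:
    return OracleAgent(latency)


def classifier_agent(profile: ClassifierProfile) -> ClassifierAgent:
    return ClassifierAgent(profile)


@dataclass(frozen=True)
class AgentConfig:
    """Serializable description of an agent (see :func:`make_agent`)."""

    kind: str
    seed: int | None = None
    spam_period: float | None = None
    oracle_latency: float | None = None
    profile: ClassifierProfile | None = None

    _KINDS = ("silent", "spam", "oracle", "classifier")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise AgentError(f"unknown agent kind {self.kind!r}")
        if self.kind == "spam" and self.spam_period is None:
            raise AgentError("spam agent requires spam_period")
        if self.kind == "classifier" and self.profile is None:
            raise AgentError("classifier agent requires a profile")

    def to_json_obj(self) -> dict:
        obj: dict = {"kind": self.kind}
        if self.seed is not None:
            obj["seed"] = self.seed
        if self.spam_period is not None:
            obj["spam_period"] = self.spam_period
        if self.oracle_latency is not None:
            obj["oracle_latency"] = self.oracle_latency
        if self.profile is not None:
            obj["profile"] = self.profile.to_json_obj()
        return obj

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "AgentConfig":
        kwargs = dict(obj)
        if "profile" in kwargs and kwargs["profile"] is not None:
            kwargs["profile"] = ClassifierProfile.from_json_obj(kwargs["profile"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise AgentError(f"malformed agent config: {exc}") from exc


def make_agent(config: AgentConfig) -> Agent:
    """Instantiate a fresh agent from its configuration."""
    if config.kind == "silent":
        return SilentAgent()
    if config.kind == "spam":
        return SpamAgent(config.spam_period)
    if config.kind == "oracle":
        return OracleAgent(config.oracle_latency or 0.0)
    return ClassifierAgent(config.profile)


def _observation(sim: RaceSimulator, t: float, params: GameParameters) -> Observation:
    pos = sim.position_at(t)
    fld = sim.current_field
    # A field is revealed when it is reachable within the preview horizon at
    # the current speed, or when the default-pace (no-command) travel time to
    # it is within the horizon.  The second rule is what guarantees that a
    # silent avatar sees every field at least `preview_horizon` seconds
    # before reaching it.
    horizon_pos = pos + sim.speed * params.preview_horizon
    upcoming = []
    default_eta = (fld.end_position - pos) / speed_of(
        SpeedState.DEFAULT, fld.kind, params)
    for f in sim.track.fields[sim.field_index + 1:]:
        if f.start_position <= horizon_pos or default_eta <= params.preview_horizon:
            upcoming.append(f.kind)
        else:
            break
        default_eta += f.length / speed_of(SpeedState.DEFAULT, f.kind, params)
    upcoming = tuple(upcoming)
    return Observation(
        time=t,
        field_index=sim.field_index,
        field_kind=fld.kind,
        distance_to_field_end=fld.end_position - pos,
        upcoming_fields=upcoming,
        state=sim.state,
        time_in_field=t - sim.per_field[-1].entry_time,
    )


def run_closed_loop(agent: Agent, track: Track, params: GameParameters,
                    seed) -> tuple[list[CommandEvent], RaceResult]:
    """Co-simulate an agent and the race engine.

    Returns the emitted command log and the race result; replaying the log
    through :func:`bcirace.engine.simulate_race` reproduces the result
    bit-identically.  ``seed`` may be anything accepted by
    :func:`numpy.random.default_rng`.
    """
    rng = np.random.default_rng(seed)
    agent.reset(rng)
    sim = RaceSimulator(track, params)
    log: list[CommandEvent] = []

    def emit(decision_time: float, cmd: Command | None) -> None:
        if cmd is None:
            return
        ev = CommandEvent(decision_time + agent.latency, cmd)
        log.append(ev)
        sim.push_command(ev)

    if agent.observes_field_entry:
        emit(0.0, agent.on_field_enter(_observation(sim, 0.0, params)))
    next_tick = 0.0 if agent.tick_period is not None else None

    while not sim.finished:
        t_event = sim.peek_next_event_time()
        if next_tick is not None and next_tick < t_event:
            emit(next_tick, agent.on_tick(_observation(sim, next_tick, params)))
            next_tick += agent.tick_period
        else:
            ev = sim.step()
            if ev.type == FIELD_ENTER:
                if agent.tick_period is not None and agent.tick_phase == "field_entry":
                    next_tick = ev.time
                if agent.observes_field_entry:
                    emit(ev.time, agent.on_field_enter(_observation(sim, ev.time, params)))

    log.sort(key=lambda e: e.time)
    return log, sim.result()
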