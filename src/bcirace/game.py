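"""Game parameters, field/track model, and track construction.

The benchmark race is run on a one-dimensional track made of typed
*fields*.  Three field kinds (spinning winds, stumbling blocks, sticky
lasers) each have one correct command (rotate, jump, slide); the fourth
kind is a *no-input* field on which any command is penalised, modelling
the idle state of an asynchronous brain-computer interface.

Units: speeds are expressed relative to the no-input default, which is
defined as 1 track-unit/s; all lengths are in track-units and times in
seconds.  Field lengths are calibrated so that a silent avatar crosses a
no-input field in 6 s and an action field in 11 s.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BciRaceError",
    "ParameterError",
    "TrackError",
    "Command",
    "FieldKind",
    "GameParameters",
    "Field",
    "Track",
    "default_parameters_2016",
    "validate_parameters",
    "build_track",
    "build_regulation_track",
    "track_from_string",
    "track_to_string",
    "REGULATION_COUNTS",
]


class BciRaceError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(BciRaceError, ValueError):
    """Invalid game-parameter set."""


class TrackError(BciRaceError, ValueError):
    """Invalid or unparsable track description."""


class Command(enum.Enum):
    """The three commands a pilot can send through the BCI."""

    ROTATE = "rotate"
    JUMP = "jump"
    SLIDE = "slide"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FieldKind(enum.Enum):
    """The four field types; the enum value is the one-letter track code."""

    NO_INPUT = "N"
    ROTATE_WIND = "R"
    JUMP_BLOCK = "J"
    SLIDE_LASER = "S"

    @property
    def is_action(self) -> bool:
        return self is not FieldKind.NO_INPUT

    @property
    def correct_command(self) -> Command | None:
        """The rewarded command on this field; ``None`` on no-input fields."""
        return _CORRECT_COMMAND[self]


_CORRECT_COMMAND: dict[FieldKind, Command | None] = {
    FieldKind.NO_INPUT: None,
    FieldKind.ROTATE_WIND: Command.ROTATE,
    FieldKind.JUMP_BLOCK: Command.JUMP,
    FieldKind.SLIDE_LASER: Command.SLIDE,
}


@dataclass(frozen=True)
class GameParameters:
    """The balancing constants of one version of the race.

    The speed parameters must obey the ordering

        s_reward_action > s_default_noinput > s_default_action
                        > s_punish_noinput = s_punish_action

    which yields the avatar's four possible speeds (high, medium default,
    low, very low).  Construction validates the ordering; use
    :meth:`unchecked` to explore deliberately unbalanced variants.
    """

    s_reward_action: float
    s_default_noinput: float
    s_default_action: float
    s_punish_noinput: float
    s_punish_action: float
    t_max_punish_noinput: float
    len_noinput: float
    len_action: float
    preview_horizon: float = 10.0

    def __post_init__(self) -> None:
        validate_parameters(self)

    @classmethod
    def unchecked(cls, **kwargs: float) -> "GameParameters":
        """Construct without validation (design-exploration escape hatch)."""
        obj = object.__new__(cls)
        for f in dataclasses.fields(cls):
            if f.name in kwargs:
                value = kwargs.pop(f.name)
            elif f.default is not dataclasses.MISSING:
                value = f.default
            else:
                raise TypeError(f"missing parameter {f.name!r}")
            object.__setattr__(obj, f.name, float(value))
        if kwargs:
            raise TypeError(f"unknown parameters: {sorted(kwargs)}")
        return obj

    def field_length(self, kind: FieldKind) -> float:
        return self.len_noinput if kind is FieldKind.NO_INPUT else self.len_action


def validate_parameters(p: GameParameters) -> GameParameters:
    """Check positivity and the speed-ordering chain; return ``p`` unchanged.

    Raises :class:`ParameterError` naming the violated constraint.
    """
    for name in ("s_reward_action", "s_default_noinput", "s_default_action",
                 "s_punish_noinput", "s_punish_action", "len_noinput", "len_action",
                 "preview_horizon"):
        value = getattr(p, name)
        if not value > 0:
            raise ParameterError(f"{name} must be strictly positive, got {value}")
    if p.t_max_punish_noinput < 0:
        raise ParameterError(
            f"t_max_punish_noinput must be >= 0, got {p.t_max_punish_noinput}")
    chain = [
        ("s_reward_action", p.s_reward_action),
        ("s_default_noinput", p.s_default_noinput),
        ("s_default_action", p.s_default_action),
        ("s_punish_noinput", p.s_punish_noinput),
    ]
    for (hi_name, hi), (lo_name, lo) in zip(chain, chain[1:]):
        if not hi > lo:
            raise ParameterError(
                f"speed ordering violated: {hi_name} > {lo_name} "
                f"requires {hi} > {lo}")
    if p.s_punish_noinput != p.s_punish_action:
        raise ParameterError(
            "s_punish_noinput must equal s_punish_action "
            f"({p.s_punish_noinput} != {p.s_punish_action}); use "
            "GameParameters.unchecked to relax")
    return p


def default_parameters_2016() -> GameParameters:
    """The parameter set used at the 2016 competition.

    Speeds are the published values (3 / 1 / 0.5 / 0.3 relative units, 4 s
    penalty window).  Field lengths are calibrated from the published
    no-command crossing times: 6 s at speed 1 on a no-input field and 11 s
    at speed 0.5 on an action field give lengths 6.0 and 5.5 track-units.
    Upcoming fields are previewed at least 10 s ahead.
    """
    return GameParameters(
        s_reward_action=3.0,
        s_default_noinput=1.0,
        s_default_action=0.5,
        s_punish_noinput=0.3,
        s_punish_action=0.3,
        t_max_punish_noinput=4.0,
        len_noinput=6.0,
        len_action=5.5,
        preview_horizon=10.0,
    )


@dataclass(frozen=True)
class Field:
    """One track segment: a kind, its length, and its cumulative start."""

    kind: FieldKind
    length: float
    start_position: float

    @property
    def end_position(self) -> float:
        return self.start_position + self.length


@dataclass(frozen=True)
class Track:
    """An ordered sequence of fields with consistent cumulative positions."""

    fields: tuple[Field, ...]

    def __post_init__(self) -> None:
        if not self.fields:
            raise TrackError("a track must contain at least one field")
        object.__setattr__(self, "fields", tuple(self.fields))
        pos = 0.0
        for i, f in enumerate(self.fields):
            if f.length <= 0:
                raise TrackError(f"field {i} has non-positive length {f.length}")
            if abs(f.start_position - pos) > 1e-9:
                raise TrackError(
                    f"field {i} starts at {f.start_position}, expected {pos}")
            pos = f.end_position

    @property
    def total_length(self) -> float:
        return self.fields[-1].end_position

    @classmethod
    def from_kinds(cls, kinds: Iterable[FieldKind], params: GameParameters) -> "Track":
        fields = []
        pos = 0.0
        for kind in kinds:
            length = params.field_length(kind)
            fields.append(Field(kind=kind, length=length, start_position=pos))
            pos += length
        return cls(fields=tuple(fields))

    def kind_counts(self) -> dict[FieldKind, int]:
        counts = {k: 0 for k in FieldKind}
        for f in self.fields:
            counts[f.kind] += 1
        return counts

    def to_json_obj(self) -> dict:
        return {
            "fields": [
                {"kind": f.kind.value, "length": f.length,
                 "start_position": f.start_position}
                for f in self.fields
            ],
            "total_length": self.total_length,
        }

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "Track":
        try:
            fields = tuple(
                Field(kind=FieldKind(fo["kind"]), length=float(fo["length"]),
                      start_position=float(fo["start_position"]))
                for fo in obj["fields"]
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise TrackError(f"malformed track JSON: {exc}") from exc
        track = cls(fields=fields)
        if "total_length" in obj and abs(obj["total_length"] - track.total_length) > 1e-9:
            raise TrackError(
                f"total_length {obj['total_length']} inconsistent with fields "
                f"(sum {track.total_length})")
        return track

    def to_json(self) -> str:
        return json.dumps(self.to_json_obj(), indent=1)


#: Regulation 2016 composition: four instances of every field kind.
REGULATION_COUNTS: dict[FieldKind, int] = {k: 4 for k in FieldKind}


def build_track(params: GameParameters, counts: Mapping[FieldKind, int],
                seed: int) -> Track:
    """Build a track with the given per-kind field counts in seeded random order.

    The composition is configurable so that unequal field frequencies (e.g.
    a 90%-idle track, closer to real assistive use) can be explored; the
    2016 regulation composition is :data:`REGULATION_COUNTS`.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise TrackError(f"seed must be a non-negative integer, got {seed!r}")
    kinds: list[FieldKind] = []
    for kind in FieldKind:  # fixed iteration order keeps the shuffle reproducible
        n = int(counts.get(kind, 0))
        if n < 0:
            raise TrackError(f"negative count for {kind.name}")
        kinds.extend([kind] * n)
    if not kinds:
        raise TrackError("track composition is empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(kinds))
    return Track.from_kinds((kinds[i] for i in order), params)


def build_regulation_track(params: GameParameters, seed: int) -> Track:
    """A regulation race layout: 16 fields, four of each kind, seeded shuffle."""
    return build_track(params, REGULATION_COUNTS, seed)


def track_from_string(spec: str, params: GameParameters) -> Track:
    """Parse a one-letter-per-field track string (alphabet N/R/J/S).

    Case-insensitive; whitespace is ignored.  Errors report the 1-based
    position of the offending character among the non-space characters.
    """
    codes = {k.value: k for k in FieldKind}
    kinds: list[FieldKind] = []
    for ch in spec:
        if ch.isspace():
            continue
        kind = codes.get(ch.upper())
        if kind is None:
            raise TrackError(
                f"unknown field code {ch!r} at position {len(kinds) + 1}")
        kinds.append(kind)
    if not kinds:
        raise TrackError("empty track string")
    return Track.from_kinds(kinds, params)


def track_to_string(track: Track) -> str:
    """Inverse of :func:`track_from_string` (up to case and whitespace)."""
    return "".join(f.kind.value for f in track.fields)
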