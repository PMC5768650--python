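"""Per-race command metrics and Monte-Carlo benchmarking.

The live competition used a single outcome per race: time to the finish
line.  A single short race is noisy, so this layer repeats closed-loop
races over seeded replicates and summarises the finish-time distribution.
It also extracts the finer per-race command metrics proposed for future
races: the number of incorrectly sent commands, the time to successfully
send a command on each action field, and the time to correct an
incorrect command.

Seeding: a master seed spawns one ``numpy.random.SeedSequence`` child per
race; from each child two 31-bit integers are drawn, the first seeding
the per-race track shuffle (when tracks are regenerated per race) and the
second the agent's random stream.  The scheme is stable across runs and
shared by all functions here, which is what makes common-random-number
comparisons (break-even search, ordering report) work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence, Union

import numpy as np

from .game import (BciRaceError, FieldKind, GameParameters, Track,
                   build_regulation_track)
from .engine import RaceResult
from .agents import (AgentConfig, ClassifierProfile, make_agent,
                     profile_from_accuracy, run_closed_loop)

__all__ = [
    "MetricsError",
    "FieldCommandMetrics",
    "MetricsReport",
    "BenchmarkSummary",
    "BreakevenResult",
    "OrderingEntry",
    "TrackPolicy",
    "race_metrics",
    "monte_carlo",
    "breakeven_accuracy",
    "ordering_report",
    "spawn_race_seeds",
]


class MetricsError(BciRaceError, ValueError):
    pass


#: A fixed track, the string "regulation" (fresh seeded regulation track per
#: race), or a callable mapping a 31-bit seed to a track.
TrackPolicy = Union[Track, str, Callable[[int], Track]]


@dataclass(frozen=True)
class FieldCommandMetrics:
    """Command timing on one action field that received at least one command.

    ``time_to_correct_command`` is the delay from field entry to the first
    correct command (``None`` if none was sent).  ``correction_time`` is
    the gap from the first incorrect command to the first subsequent
    correct one, i.e. how long the standing error persisted; it is present
    only when an incorrect command preceded a correct one.
    """

    field_index: int
    time_to_correct_command: float | None
    correction_time: float | None


@dataclass(frozen=True)
class MetricsReport:
    incorrect_command_count: int
    per_action_field: tuple[FieldCommandMetrics, ...]
    noinput_false_positives: int

    def to_json_obj(self) -> dict:
        return {
            "incorrect_command_count": self.incorrect_command_count,
            "noinput_false_positives": self.noinput_false_positives,
            "per_action_field": [
                {"field_index": m.field_index,
                 "time_to_correct_command": m.time_to_correct_command,
                 "correction_time": m.correction_time}
                for m in self.per_action_field
            ],
        }


def race_metrics(result: RaceResult, track: Track) -> MetricsReport:
    """Extract the per-race command metrics from a race trace.

    Every command on a no-input field and every wrong command on an action
    field counts as incorrect, so the incorrect count equals the total
    number of emitted commands minus the correct-on-action-field ones.
    """
    if len(result.per_field) != len(track.fields):
        raise MetricsError(
            f"result covers {len(result.per_field)} fields but the track has "
            f"{len(track.fields)}")
    incorrect = 0
    false_positives = 0
    per_action: list[FieldCommandMetrics] = []
    for crossing, fld in zip(result.per_field, track.fields):
        cmds = crossing.commands_received
        if fld.kind is FieldKind.NO_INPUT:
            incorrect += len(cmds)
            false_positives += len(cmds)
            continue
        correct = fld.kind.correct_command
        incorrect += sum(1 for c in cmds if c.command is not correct)
        if not cmds:
            continue
        first_correct = next(
            (c.time for c in cmds if c.command is correct), None)
        time_to_correct = (first_correct - crossing.entry_time
                           if first_correct is not None else None)
        wrong_before = [
            c.time for c in cmds
            if c.command is not correct
            and (first_correct is None or c.time < first_correct)]
        correction = (first_correct - wrong_before[0]
                      if first_correct is not None and wrong_before else None)
        per_action.append(FieldCommandMetrics(
            field_index=crossing.field_index,
            time_to_correct_command=time_to_correct,
            correction_time=correction))
    return MetricsReport(
        incorrect_command_count=incorrect,
        per_action_field=tuple(per_action),
        noinput_false_positives=false_positives)


@dataclass(frozen=True)
class BenchmarkSummary:
    """Distributional summary of repeated closed-loop races."""

    n_races: int
    mean_finish: float
    sd_finish: float
    quantiles: tuple[float, float, float]  # 5%, 50%, 95%
    mean_incorrect_commands: float
    seeds_used: tuple[tuple[int, int], ...]  # (track_seed, agent_seed) per race

    def to_json_obj(self) -> dict:
        return {
            "n_races": self.n_races,
            "mean_finish": self.mean_finish,
            "sd_finish": self.sd_finish,
            "quantiles": {"q05": self.quantiles[0], "q50": self.quantiles[1],
                          "q95": self.quantiles[2]},
            "mean_incorrect_commands": self.mean_incorrect_commands,
            "seeds_used": [list(pair) for pair in self.seeds_used],
        }


def spawn_race_seeds(master_seed: int, n_races: int) -> tuple[tuple[int, int], ...]:
    """Deterministically derive (track_seed, agent_seed) pairs per race."""
    root = np.random.SeedSequence(master_seed)
    pairs = []
    for child in root.spawn(n_races):
        track_word, agent_word = child.generate_state(2)
        pairs.append((int(track_word) & 0x7FFFFFFF, int(agent_word) & 0x7FFFFFFF))
    return tuple(pairs)


def _resolve_track(policy: TrackPolicy, params: GameParameters,
                   track_seed: int) -> Track:
    if isinstance(policy, Track):
        return policy
    if policy == "regulation":
        return build_regulation_track(params, track_seed)
    if callable(policy):
        return policy(track_seed)
    raise MetricsError(f"unknown track policy {policy!r}")


def _run_races(agent_config: AgentConfig, track_policy: TrackPolicy,
               params: GameParameters,
               seed_pairs: Sequence[tuple[int, int]]
               ) -> tuple[np.ndarray, np.ndarray]:
    finishes = np.empty(len(seed_pairs))
    incorrect = np.empty(len(seed_pairs))
    for k, (track_seed, agent_seed) in enumerate(seed_pairs):
        track = _resolve_track(track_policy, params, track_seed)
        agent = make_agent(agent_config)
        _, result = run_closed_loop(agent, track, params, agent_seed)
        finishes[k] = result.finish_time
        incorrect[k] = race_metrics(result, track).incorrect_command_count
    return finishes, incorrect


def monte_carlo(agent_config: AgentConfig, track_policy: TrackPolicy,
                params: GameParameters, n_races: int,
                master_seed: int) -> BenchmarkSummary:
    """Run seeded closed-loop replicates and summarise finish times."""
    if n_races < 1:
        raise MetricsError(f"n_races must be >= 1, got {n_races}")
    pairs = spawn_race_seeds(master_seed, n_races)
    finishes, incorrect = _run_races(agent_config, track_policy, params, pairs)
    sd = float(np.std(finishes, ddof=1)) if n_races > 1 else 0.0
    q05, q50, q95 = np.quantile(finishes, [0.05, 0.5, 0.95])
    return BenchmarkSummary(
        n_races=n_races,
        mean_finish=float(np.mean(finishes)),
        sd_finish=sd,
        quantiles=(float(q05), float(q50), float(q95)),
        mean_incorrect_commands=float(np.mean(incorrect)),
        seeds_used=pairs)


@dataclass(frozen=True)
class BreakevenResult:
    """Outcome of the break-even accuracy search.

    ``status`` is ``"converged"`` (``accuracy`` is the bisection upper
    bracket, the smallest accuracy known to beat the silent baseline),
    ``"below_range"`` (chance-level accuracy already beats silence) or
    ``"out_of_range"`` (even a perfect classifier does not beat silence;
    ``accuracy`` is ``None``).
    """

    accuracy: float | None
    status: str
    silent_mean: float
    n_races: int
    evaluations: tuple[tuple[float, float], ...]  # (accuracy, mean finish)


def breakeven_accuracy(params: GameParameters,
                       profile_template: ClassifierProfile,
                       track_policy: TrackPolicy, n_races: int, tol: float,
                       master_seed: int) -> BreakevenResult:
    """Smallest command accuracy whose mean finish beats the silent baseline.

    The template's rest row (false-positive behaviour) and timing are kept
    fixed; the three command rows are rebuilt at each candidate accuracy
    ``a`` with ``a`` on the diagonal and (1-a)/2 on the two wrong-command
    columns.  All evaluations and the silent baseline share one set of
    race seeds (common random numbers), and the search bisects over
    [1/3, 1] until the bracket is narrower than ``tol``.
    """
    if tol <= 0:
        raise MetricsError(f"tol must be positive, got {tol}")
    pairs = spawn_race_seeds(master_seed, n_races)
    silent_finishes, _ = _run_races(AgentConfig(kind="silent"), track_policy,
                                    params, pairs)
    silent_mean = float(np.mean(silent_finishes))
    evaluations: list[tuple[float, float]] = []

    def mean_finish(a: float) -> float:
        m = np.array(profile_template.confusion, copy=True)
        for r in range(3):
            m[r, :3] = (1.0 - a) / 2.0
            m[r, r] = a
            m[r, 3] = 0.0
        profile = replace(profile_template, confusion=m)
        config = AgentConfig(kind="classifier", profile=profile)
        finishes, _ = _run_races(config, track_policy, params, pairs)
        mean = float(np.mean(finishes))
        evaluations.append((a, mean))
        return mean

    lo, hi = 1.0 / 3.0, 1.0
    if mean_finish(hi) > silent_mean:
        return BreakevenResult(None, "out_of_range", silent_mean, n_races,
                               tuple(evaluations))
    if mean_finish(lo) <= silent_mean:
        return BreakevenResult(lo, "below_range", silent_mean, n_races,
                               tuple(evaluations))
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_finish(mid) <= silent_mean:
            hi = mid
        else:
            lo = mid
    return BreakevenResult(hi, "converged", silent_mean, n_races,
                           tuple(evaluations))


@dataclass(frozen=True)
class OrderingEntry:
    label: str
    mean_finish: float
    se_finish: float


def ordering_report(params: GameParameters,
                    configs: Mapping[str, AgentConfig],
                    track_policy: TrackPolicy, n_races: int,
                    master_seed: int) -> list[OrderingEntry]:
    """Empirical mean finish times per labelled agent, fastest first.

    All agents race on matched per-race seeds.  The report *orders*, it
    does not assert a particular ranking: whether silence really beats
    random command spam depends on the spam rate and the track's
    no-input/action composition, so the question is answered empirically.
    """
    if not configs:
        raise MetricsError("configs must not be empty")
    pairs = spawn_race_seeds(master_seed, n_races)
    entries = []
    for label, config in configs.items():
        finishes, _ = _run_races(config, track_policy, params, pairs)
        se = (float(np.std(finishes, ddof=1)) / np.sqrt(n_races)
              if n_races > 1 else 0.0)
        entries.append(OrderingEntry(label=label,
                                     mean_finish=float(np.mean(finishes)),
                                     se_finish=se))
    entries.sort(key=lambda e: e.mean_finish)
    return entries
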