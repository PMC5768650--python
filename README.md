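# bcirace

An event-driven simulator and Monte-Carlo benchmark for the **Cybathlon
BrainRunners race**, the racing game used to benchmark asynchronous
brain-computer interfaces (BCIs) by task completion time.

## The problem and who this is for

In the BrainRunners race a pilot steers an avatar over a track of 16
fields — four *no-input* fields, on which any command is penalised
(modelling the idle state every asynchronous BCI needs), and four
instances each of three *action* fields, on which exactly one of the
commands **rotate**, **jump**, **slide** is rewarded.  The only outcome
of a race is the time to the finish line.  A single live race, however,
confounds BCI quality with luck: it is short, the field order is random,
and a handful of misclassifications can dominate the result.

This package is for BCI researchers and competition designers who want to
ask, *before* fielding human pilots: how do classifier accuracy, decision
rate, latency and false-positive rate map to race-time distributions?  Is
the reward/penalty structure balanced so that a realistic BCI beats doing
nothing, and doing nothing beats random commands?  What is the break-even
accuracy for a given false-positive rate?

## The model

The avatar moves at a piecewise-constant speed set by a
(speed-state, field-kind) pair.  With the six balancing parameters of the
2016 game,

    s_reward,Action = 3 > s_default,NoInput = 1 > s_default,Action = 0.5
                    > s_punish,NoInput = s_punish,Action = 0.3,
    t_maxPunish,NoInput = 4 s,

the four possible speeds are: high (correct command on an action field),
medium default (silent on no-input), low (silent on an action field) and
very low (wrong command on an action field, or any command on no-input —
the latter for at most 4 s).  Within a field a later command overrides
the current effect; entering a new field resets to the default.  Field
lengths are calibrated from the published crossing times (a silent avatar
needs 6 s per no-input field and 11 s per action field), giving 6.0 and
5.5 track-units at a unit no-input speed.  Upcoming fields are previewed
at least 10 s ahead.

Because speeds are piecewise constant, motion is integrated *exactly* by
an event-driven sweep over command arrivals, penalty expirations and
field boundaries — no time-stepping error.  Pilot models (silent, random
spam, latency-parameterised oracle, and a confusion-matrix classifier
with decision period, latency, entry-delay strategy and command subset)
close the loop, and a benchmarking layer runs seeded Monte-Carlo
replicates, extracts per-race command metrics (incorrect-command count,
time-to-correct-command per action field, error-correction time) and
searches for the break-even accuracy against the silent baseline.

## Worked example

```sh
$ bcirace simulate --track-string NJRS
finish_time_s=39.000
```

One no-input field (6 s) plus three silent action fields (3 × 11 s): a
silent avatar needs 39 s.  Now a regulation track and a realistic pilot —
80% command accuracy, 10% false-positive rate per 0.5 s decision:

```sh
$ bcirace track-gen --seed 7 --out track7.json      # NJRJNSNRRSSNSRJJ
$ bcirace benchmark --track track7.json --agent agent.json \
      --n-races 200 --seed 42
{
 "n_races": 200,
 "mean_finish": 73.35208333333333,
 "sd_finish": 11.390402909503024,
 "quantiles": {"q05": 56.199..., "q50": 71.816..., "q95": 94.523...},
 "mean_incorrect_commands": 14.355,
 ...
}
```

The pilot averages 73.4 s — between the zero-latency oracle (46.0 s) and
the silent baseline (156.0 s) — with a 90% interval of roughly 56–95 s
and about 14 incorrect commands per race: the spread of a *single* live
race spans tens of seconds, which is why the benchmark averages many.

Is silence really better than random spamming?  Quantified over spam
periods on fresh regulation tracks:

```sh
$ bcirace ordering --regulation-per-race --n-races 100 --seed 42
   spam_0.5s  mean= 136.815 s  se=0.571
     spam_1s  mean= 141.786 s  se=0.779
     spam_2s  mean= 144.543 s  se=1.628
      silent  mean= 156.000 s  se=0.000
     spam_5s  mean= 161.095 s  se=1.920
```

Under the 2016 parameters and the 4-no-input/12-action composition,
*fast* random spam beats silence (a random command is rewarded 1/3 of the
time on the twelve action fields, which outweighs the bounded no-input
penalties); only slow spam loses.  The claimed silent-over-spam ordering
is rate- and composition-dependent — exactly the kind of balance question
the simulator is built to answer (see `docs/methods.md`).

## Layout

- `src/bcirace/game.py` — parameters, validation, fields, track
  construction and (de)serialisation
- `src/bcirace/engine.py` — event-driven race dynamics plus a fixed-step
  cross-check integrator
- `src/bcirace/agents.py` — pilot models and the closed-loop harness
- `src/bcirace/benchmark.py` — per-race command metrics, Monte-Carlo
  summaries, break-even accuracy search, ordering report
- `src/bcirace/formats.py`, `src/bcirace/cli.py` — CSV/JSON/key=value
  formats and the `bcirace` command-line tool
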