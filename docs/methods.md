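# Methods

## Game dynamics

The race is a deterministic hybrid system: continuous one-dimensional
motion at a piecewise-constant speed, with discrete jumps driven by three
event types — command arrivals, the no-input penalty-timer expiration,
and field-boundary crossings.  The speed is a function of the avatar's
speed state (DEFAULT, REWARD, PENALTY) and the current field kind:

| state \ field | no-input            | action (rotate/jump/slide) |
|---------------|---------------------|----------------------------|
| DEFAULT       | `s_default_noinput` | `s_default_action`         |
| REWARD        | unreachable         | `s_reward_action`          |
| PENALTY       | `s_punish_noinput`  | `s_punish_action`          |

Command semantics: on an action field the correct command sets REWARD and
any other command sets PENALTY, each overriding the previous effect and
lasting to the end of the field; on a no-input field every command sets
PENALTY for `t_max_punish_noinput` seconds.  Validation enforces the
balance ordering `s_reward_action > s_default_noinput > s_default_action
> s_punish_noinput = s_punish_action` (an `unchecked` constructor exists
for exploring unbalanced variants).

Because speeds are piecewise constant the engine integrates motion
exactly: it repeatedly advances to the earliest of the next command, the
penalty expiration and the current field's end, computed in closed form.
All arithmetic is double precision with no rounding of event times;
"exact" baselines such as the 46 s zero-latency oracle are therefore
reproduced to floating-point accumulation error (~1e-13 relative), and
tests assert them at 1e-9 absolute.

Deliberate rule choices where the published description is silent:

* **Boundary tie-break.** Position intervals are half-open `[start, end)`;
  at equal timestamps a boundary crossing is processed before a command,
  so a command arriving exactly at a boundary applies to the field being
  entered.  Penalty expiration sits between the two.
* **Cross-field penalty truncation.** Entering a new field always resets
  the state to DEFAULT and cancels a pending no-input penalty timer, the
  simplest reading of "effects last until the end of the field".
* **Timer restart.** Each command on a no-input field restarts the
  penalty timer at its maximum; penalties neither stack nor queue.
* **Idempotent reward.** Re-sending the active correct command keeps
  REWARD.

## Parameters and calibration

`default_parameters_2016()` uses the published relative speeds
(3 / 1 / 0.5 / 0.3) and 4 s penalty window, with `s_default_noinput = 1`
defining the unit system (one track-unit per second).  Field lengths were
not published; they are calibrated from the published silent crossing
times — 6 s per no-input field and 11 s per action field — giving
`len_noinput = 6.0` and `len_action = 5.5` units.  The crossing times are
treated as exact even though they were reported as approximate; every
derived timing in this package (regulation silent baseline 156 s,
zero-latency oracle 46 s, total length 90 units) inherits that
calibration assumption.  Track composition is configurable per kind;
"regulation" (four of each of the four kinds, seeded uniform shuffle) is
a named preset, and idle-heavy compositions can be built directly.

## Preview model

Fields are revealed to the pilot when either (a) their start is within
`preview_horizon` seconds of travel at the *current* speed, or (b) the
default-pace (no-command) travel time to their start is within the
horizon.  Rule (b) is what guarantees that a silent avatar sees every
field at least 10 s before reaching it: rule (a) alone fails near the end
of a slow action field, where a field only 5 units ahead can be reached
in under 10 s once the avatar returns to the unit default speed.  A
rewarded avatar can still arrive in fewer wall-clock seconds than the
horizon; the guarantee is at default pace, matching how the game's fixed
preview distance behaves for a nominal runner.

## Pilot models

* **silent** — never commands; the guaranteed-finish baseline.
* **spam(period)** — a uniformly random command at every multiple of the
  period from race start, modelling blind guessing.
* **oracle(latency)** — the correct command exactly `latency` seconds
  after entering each action field; the performance envelope.
* **classifier(profile)** — an asynchronous-BCI model.  At each decision
  tick the pilot holds an *intent* (one command or rest); the emitted
  output is sampled from the intent's row of a 4x4 row-stochastic
  confusion matrix whose columns are the three commands plus "no output".
  Rest-row mass on command columns is the sole source of no-input false
  positives.  The intent policy — intend the field's correct command
  (after `entry_delay`, and only if it is in `command_subset`), rest
  otherwise, stop once REWARD is achieved on the field — is one plausible
  strategy, not a recorded fact about real pilots; the strategy surface
  is exposed through the profile parameters.

Classifier decision ticks are phased to field entry (first tick on
entering a field, then every `decision_period`, default 0.5 s — a typical
sub-second asynchronous update rate, configurable).  The phasing reflects
the field-driven intent policy and makes the degenerate equivalences
exact: an identity confusion matrix reproduces the zero-latency oracle
bit-for-bit, and an all-"no output" matrix reproduces the silent
baseline.  The spam agent keeps a global tick grid, as befits a pilot who
ignores the track.

The closed-loop harness anchors the engine state at the last processed
event and evaluates observations as affine functions of time, so
observing never perturbs the integrator: replaying the emitted command
log open-loop reproduces the closed-loop result bit-identically.

## Monte-Carlo benchmarking

A master seed spawns one `numpy.random.SeedSequence` child per race; each
child yields a 31-bit track seed (used when tracks are regenerated per
race) and a 31-bit agent seed.  Summaries report mean, sample standard
deviation, 5/50/95% quantiles and the mean incorrect-command count; the
per-race seed pairs are recorded in the summary for replay.

The break-even search finds the smallest command accuracy whose mean
finish beats the silent baseline, holding the template's rest row and
timing fixed and rebuilding the three command rows at each candidate
accuracy `a` (diagonal `a`, `(1-a)/2` on each wrong command).  It bisects
over [1/3, 1] with *common random numbers* — every evaluation and the
silent baseline reuse one set of race seeds — which removes most
Monte-Carlo noise from the comparison; `tol` and `n_races` are
caller-controlled.  Outcomes below the sweep (chance level already beats
silence) or above it (even a perfect classifier loses) are reported as
statuses, not errors: both occur, depending on the false-positive rate
and track composition.

Per-race command metrics: the incorrect-command count (every command on a
no-input field plus every wrong command on an action field, so it equals
total commands minus correct-on-action ones); per action field that
received at least one command, the delay from entry to the first correct
command; and, when an incorrect command preceded the first correct one,
the correction time — measured from the *first* incorrect command before
the first correct one, i.e. how long the standing error persisted.

## Properties that hold, and one that does not

Exact, fuzz-tested properties: per-field durations chain and sum to the
finish time; observed trace speeds take only the four values; delaying
the sole correct command on an action field never decreases its benefit;
the event-driven engine agrees with an independent fixed-step integrator
(which splits steps only at command/expiration instants and caps motion
at boundaries) to well under 2 ms at a 1 ms step.

Penalty monotonicity — "an extra incorrect command never speeds up the
race" — holds only when the extra command arrives at or after the last
command of the log (then the post-insertion dynamics are a pure time
shift of the unperturbed run, so the finish can only move later).  It is
*false* for mid-log insertions: with fixed command timestamps, slowing
the avatar can re-align a later command with its correct field.  Concrete
case (in the test suite): on track `RN` with a lone `rotate` at 11.5 s,
the base run finishes in 19.8 s (the rotate is a false positive on the
no-input field); adding a *wrong* `jump` at 1.0 s keeps the avatar on the
rotate field until past 11.5 s, the rotate now rewards, and the race
finishes in ~18.1 s.  This is a real feature of timestamp-replay
semantics, not an engine artefact: open-loop logs do not adapt to the
avatar's position the way a closed-loop pilot does.

## What the synthetic conditions do and do not show

All inputs are synthetic: tracks from the published composition rules,
command streams from the agent models.  The confusion-matrix pilot
assumes i.i.d. classifier outputs at a fixed rate with stationary
accuracy — no fatigue, learning, artefacts, or serially correlated EEG
decoding errors — and the intent policy is an idealised strategy.
Passing benchmarks therefore validate the *game mechanics and their
balance*, and give upper-bound-style intuition for how BCI quality maps
to race time; they do not predict any particular human pilot's time.
Notably, at the 2016 parameters with 4 no-input vs 12 action fields, the
benchmark shows mean finish time for random spam at periods <= 2 s
*below* the 156 s silent baseline (e.g. ~137 s at 0.5 s period, n = 100
races), while 5 s spam is worse (~161 s): the silent-over-spam balance
claim holds only for slow spam under this composition, and idle-heavy
tracks reverse it.  The ordering report treats this as an empirical,
parameter-dependent question.

## Problem sizes

Default study sizes keep every analysis at desk scale: benchmark
summaries and ordering reports use 100–200 races (standard error of the
mean finish ~0.5–2 s for stochastic agents), and the break-even search
uses a few hundred races per bisection step with common random numbers.
Fuzz suites run 1,000 cases against the fixed-step oracle at a 1 ms step
and 1,000 monotonicity cases.
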