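import numpy as np
import pytest

from bcirace import (AgentConfig, AgentError, ClassifierProfile, Command,
                     classifier_agent, identity_profile, make_agent,
                     oracle_agent, profile_from_accuracy, run_closed_loop,
                     silent_agent, simulate_race, spam_agent,
                     track_from_string, build_regulation_track)
from bcirace.agents import _observation
from bcirace.engine import RaceSimulator

from conftest import random_case

ALL_NONE = np.column_stack([np.zeros((4, 3)), np.ones(4)])


class TestSilent:
    def test_no_commands_and_baseline_times(self, params, regulation_track):
        log, result = run_closed_loop(silent_agent(), regulation_track,
                                      params, seed=0)
        assert log == []
        assert result.finish_time == pytest.approx(156.0, abs=1e-9)

    def test_single_noinput_field(self, params):
        _, result = run_closed_loop(silent_agent(),
                                    track_from_string("N", params), params, 0)
        assert result.finish_time == 6.0


class TestSpam:
    def test_deterministic_per_seed(self, params, regulation_track):
        a = run_closed_loop(spam_agent(1.0), regulation_track, params, 5)
        b = run_closed_loop(spam_agent(1.0), regulation_track, params, 5)
        assert a[0] == b[0]
        assert a[1].finish_time == b[1].finish_time

    def test_perpetual_penalty_on_noinput_field(self, params):
        # commands at 0,1,2,... keep restarting the 4 s penalty timer
        _, result = run_closed_loop(spam_agent(1.0),
                                    track_from_string("N", params), params, 3)
        assert result.finish_time == pytest.approx(6.0 / 0.3)

    def test_rejects_nonpositive_period(self):
        with pytest.raises(AgentError):
            spam_agent(0.0)


class TestOracle:
    def test_zero_latency_regulation_baseline(self, params, regulation_track):
        log, result = run_closed_loop(oracle_agent(0.0), regulation_track,
                                      params, 0)
        assert result.finish_time == pytest.approx(46.0, abs=1e-9)
        assert len(log) == 12  # one correct command per action field

    @pytest.mark.parametrize("latency,expected", [
        (0.0, 5.5 / 3),
        (2.0, 2 + 4.5 / 3),
    ])
    def test_latency_on_single_action_field(self, params, latency, expected):
        _, result = run_closed_loop(oracle_agent(latency),
                                    track_from_string("J", params), params, 0)
        assert result.finish_time == pytest.approx(expected, abs=1e-9)

    def test_rejects_negative_latency(self):
        with pytest.raises(AgentError):
            oracle_agent(-1.0)


class TestClassifierProfile:
    def test_rejects_non_stochastic_rows(self):
        m = np.eye(4)
        m[0, 0] = 0.5
        with pytest.raises(AgentError, match="sum to 1"):
            ClassifierProfile(confusion=m)

    def test_rejects_negative_entries(self):
        m = np.eye(4)
        m[0, 0] = 1.5
        m[0, 1] = -0.5
        with pytest.raises(AgentError, match="non-negative"):
            ClassifierProfile(confusion=m)

    def test_rejects_bad_timing(self):
        with pytest.raises(AgentError):
            identity_profile(decision_period=0.0)

    def test_accuracy_profile_rows(self):
        p = profile_from_accuracy(0.8, false_positive_rate=0.3)
        assert p.confusion[1].tolist() == pytest.approx([0.1, 0.8, 0.1, 0.0])
        assert p.confusion[3].tolist() == pytest.approx([0.1, 0.1, 0.1, 0.7])

    def test_json_round_trip(self):
        p = profile_from_accuracy(0.8, 0.1, decision_period=0.25, latency=0.5,
                                  entry_delay=1.0,
                                  command_subset={Command.JUMP})
        q = ClassifierProfile.from_json_obj(p.to_json_obj())
        assert np.array_equal(p.confusion, q.confusion)
        assert (q.decision_period, q.latency, q.entry_delay) == (0.25, 0.5, 1.0)
        assert q.command_subset == frozenset({Command.JUMP})


class TestClassifierAgent:
    def test_perfect_profile_matches_oracle_bit_exactly(self, params,
                                                        regulation_track):
        log_o, res_o = run_closed_loop(oracle_agent(0.0), regulation_track,
                                       params, 0)
        log_c, res_c = run_closed_loop(classifier_agent(identity_profile()),
                                       regulation_track, params, 0)
        assert log_c == log_o
        assert res_c.finish_time == res_o.finish_time

    def test_all_none_profile_matches_silent_bit_exactly(self, params,
                                                         regulation_track):
        log, res = run_closed_loop(
            classifier_agent(ClassifierProfile(confusion=ALL_NONE)),
            regulation_track, params, 0)
        _, res_s = run_closed_loop(silent_agent(), regulation_track, params, 0)
        assert log == []
        assert res.finish_time == res_s.finish_time

    def test_quiet_rest_row_never_fires_on_noinput(self, params):
        track = track_from_string("NNNN", params)
        profile = profile_from_accuracy(0.5, false_positive_rate=0.0)
        log, result = run_closed_loop(classifier_agent(profile), track,
                                      params, 9)
        assert log == []
        assert result.finish_time == 24.0

    def test_command_subset_restricts_intents(self, params):
        # a jump-only pilot rests on rotate/slide fields
        profile = identity_profile(command_subset={Command.JUMP})
        track = track_from_string("RJS", params)
        log, _ = run_closed_loop(classifier_agent(profile), track, params, 0)
        assert [e.command for e in log] == [Command.JUMP]

    def test_entry_delay_postpones_first_command(self, params):
        profile = identity_profile(entry_delay=1.5)
        track = track_from_string("J", params)
        log, result = run_closed_loop(classifier_agent(profile), track,
                                      params, 0)
        # first tick at/after 1.5 s on a 0.5 s grid anchored at field entry
        assert log[0].time == pytest.approx(1.5)
        assert result.finish_time == pytest.approx(1.5 + (5.5 - 0.75) / 3)

    def test_stops_commanding_after_reward(self, params):
        log, _ = run_closed_loop(classifier_agent(identity_profile()),
                                 track_from_string("J", params), params, 0)
        assert len(log) == 1

    def test_mean_finish_between_oracle_and_silent(self, params,
                                                   regulation_track):
        profile = profile_from_accuracy(0.8, false_positive_rate=0.1)
        finishes = []
        for seed in range(100):
            _, res = run_closed_loop(classifier_agent(profile),
                                     regulation_track, params, seed)
            finishes.append(res.finish_time)
        mean = np.mean(finishes)
        assert 46.0 < mean < 156.0


class TestClosedLoopHarness:
    def test_replay_reproduces_closed_loop_exactly(self, params):
        rng = np.random.default_rng(21)
        for _ in range(50):
            track, _ = random_case(rng, params, max_commands=0)
            profile = profile_from_accuracy(
                float(rng.uniform(0.34, 1.0)),
                false_positive_rate=float(rng.uniform(0.0, 0.5)),
                decision_period=float(rng.uniform(0.2, 1.5)),
                latency=float(rng.uniform(0.0, 1.0)))
            log, res = run_closed_loop(classifier_agent(profile), track,
                                       params, int(rng.integers(2**31)))
            replay = simulate_race(track, params, log)
            assert replay.finish_time == res.finish_time  # bit-identical

    def test_same_seed_identical_run(self, params, regulation_track):
        profile = profile_from_accuracy(0.6, 0.2)
        a = run_closed_loop(classifier_agent(profile), regulation_track,
                            params, 77)
        b = run_closed_loop(classifier_agent(profile), regulation_track,
                            params, 77)
        assert a[0] == b[0]
        assert a[1].finish_time == b[1].finish_time

    def test_observation_respects_preview_horizon(self, params):
        # on NJJN at t=0: the first J (6 units, 6 s away at default pace)
        # is visible; everything past it (>= 11.5 units, 17 s) is hidden
        track = track_from_string("NJJN", params)
        sim = RaceSimulator(track, params)
        obs = _observation(sim, 0.0, params)
        assert obs.upcoming_fields == (track.fields[1].kind,)
        assert obs.field_kind == track.fields[0].kind
        assert obs.distance_to_field_end == 6.0
        # an avatar on a slow action field sees nothing 11 s away
        track2 = track_from_string("JN", params)
        sim2 = RaceSimulator(track2, params)
        assert _observation(sim2, 0.0, params).upcoming_fields == ()


class TestAgentConfig:
    def test_round_trip_and_factory(self):
        cfg = AgentConfig(kind="classifier",
                          profile=profile_from_accuracy(0.9, 0.05))
        again = AgentConfig.from_json_obj(cfg.to_json_obj())
        assert again.kind == "classifier"
        assert np.array_equal(again.profile.confusion, cfg.profile.confusion)
        assert make_agent(again).tick_period == 0.5

    def test_missing_subfields_rejected(self):
        with pytest.raises(AgentError):
            AgentConfig(kind="spam")
        with pytest.raises(AgentError):
            AgentConfig(kind="classifier")
        with pytest.raises(AgentError):
            AgentConfig(kind="warp")
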