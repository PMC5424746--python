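"""Control-strategy FSM: ADC averaging, spike removal, voting, actuation."""

import numpy as np
import pytest

from emgctl import (
    ControllerConfig,
    Gesture,
    HandSim,
    acquire_frame,
    gen_contraction,
    gen_rest,
    gen_session,
    inject_spike,
    majority_vote,
    run_controller,
    spike_filter_step,
)
from emgctl.controller import ControllerState, FsmNode
from emgctl.synth import concat_streams, default_profiles

OPEN, POWER, POINT, PRECISION = (Gesture.OPEN_HAND, Gesture.POWER_GRASP,
                                 Gesture.POINT_INDEX, Gesture.PRECISION_GRASP)


class TestAdcAcquisition:
    def test_mean_of_constant_samples(self):
        raw = np.full((16, 4), 0.7)
        assert np.allclose(acquire_frame(raw), 0.7)

    def test_arithmetic_mean(self):
        raw = np.zeros((16, 4))
        raw[:, 0] = np.arange(1, 17)
        assert acquire_frame(raw)[0] == pytest.approx(8.5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 3.3, (16, 4))
        shuffled = raw[rng.permutation(16)]
        assert np.allclose(acquire_frame(raw), acquire_frame(shuffled))

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ValueError):
            acquire_frame(np.zeros((8, 4)))


class TestMajorityVote:
    def test_unanimity(self):
        assert majority_vote([POWER] * 20) is POWER

    def test_strict_majority(self):
        assert majority_vote([POINT] * 11 + [POWER] * 9) is POINT

    def test_tie_resolves_to_lowest_index(self):
        assert majority_vote([POWER] * 10 + [POINT] * 10) is POWER

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestSpikeFilter:
    def make_state(self):
        return ControllerState()

    def run_frames(self, state, activations, config):
        frame = lambda a: np.array([a, 0.0, 0.0, 0.0])
        for a in activations:
            state = spike_filter_step(state, frame(a), config)
            if state.node is FsmNode.VOTING:
                break
        return state

    def test_short_burst_discarded(self):
        cfg = ControllerConfig()
        st = self.run_frames(self.make_state(), [1.0] * 40 + [0.0], cfg)
        assert st.node is FsmNode.IDLE
        assert st.above_threshold_frames == 0

    def test_hundred_ms_boundary_triggers(self):
        cfg = ControllerConfig()
        st = self.run_frames(self.make_state(), [1.0] * 50, cfg)
        assert st.node is FsmNode.VOTING

    def test_forty_nine_frames_do_not_trigger(self):
        cfg = ControllerConfig()
        st = self.run_frames(self.make_state(), [1.0] * 49, cfg)
        assert st.node is FsmNode.ONSET_CHECK

    def test_baseline_never_leaves_idle(self):
        cfg = ControllerConfig()
        st = self.run_frames(self.make_state(), [0.05] * 200, cfg)
        assert st.node is FsmNode.IDLE

    def test_spike_frame_count_config(self):
        assert ControllerConfig().spike_frames == 50
        with pytest.raises(ValueError):
            ControllerConfig(spike_min_duration_ms=100.7)


class TestHandSim:
    def test_precision_grasp_closes_thumb_and_index_only(self):
        hand = HandSim()
        hand.actuate(PRECISION)
        assert hand.finger_position["thumb"] == 1.0
        assert hand.finger_position["index"] == 1.0
        for f in ("middle", "ring", "little"):
            assert hand.finger_position[f] == 0.0

    def test_point_index_extends_index(self):
        hand = HandSim()
        hand.actuate(POINT)
        assert hand.finger_position["index"] == 0.0
        assert all(hand.finger_position[f] == 1.0
                   for f in ("thumb", "middle", "ring", "little"))

    def test_open_resets_all_fingers_from_any_position(self):
        hand = HandSim()
        hand.actuate(POWER)
        hand.actuate(OPEN)
        assert hand.is_open

    def test_object_blocks_closing_at_its_width(self):
        hand = HandSim(object_width=0.6)
        hand.actuate(POWER)
        assert all(p == 0.6 for p in hand.finger_position.values())
        # the stall transient exceeded the current threshold, motor now off
        assert all(c == 0.0 for c in hand.motor_current.values())

    def test_gesture_from_non_open_hand_rejected(self):
        hand = HandSim()
        hand.actuate(POWER)
        with pytest.raises(RuntimeError):
            hand.actuate(PRECISION)

    def test_motor_time_scales_with_travel(self):
        hand = HandSim()
        t_full = hand.actuate(POWER)
        hand2 = HandSim(object_width=0.5)
        t_half = hand2.actuate(POWER)
        assert t_half == pytest.approx(t_full / 2)


def run_session(profiles, model, mode, reps=2, seed=0, config=None):
    stream, intended = gen_session(profiles, reps=reps, seed=seed)
    cfg = config or ControllerConfig(mode=mode)
    return stream, intended, run_controller(stream, model, cfg, HandSim())


class TestControllerRuns:
    def test_noiseless_session_executes_intended_exactly(
            self, clean_profiles, complete_model):
        _, intended, run = run_session(clean_profiles, complete_model,
                                       "COMPLETE", reps=2)
        assert run.executed_labels == intended

    def test_decision_latency_is_40ms(self, clean_profiles, complete_model):
        _, _, run = run_session(clean_profiles, complete_model, "COMPLETE",
                                reps=1)
        starts = [t for t, e in run.events if e == "voting_start"]
        decisions = [t for t, e in run.events if e.startswith("decision")]
        assert len(starts) == len(decisions) > 0
        for t0, t1 in zip(starts, decisions):
            assert t1 - t0 == pytest.approx(40.0)

    def test_onset_to_actuation_bound(self, clean_profiles, complete_model):
        # threshold crossing -> actuation within 100 ms filter + 40 ms vote
        stream, _, run = run_session(clean_profiles, complete_model,
                                     "COMPLETE", reps=1)
        cfg = ControllerConfig()
        first_act = run.executed[0][0]
        above = stream.t_ms[stream.channels.max(axis=1)
                            >= cfg.activation_threshold]
        assert first_act - above[0] <= 100.0 + 40.0 + 1e-9

    def test_spike_during_rest_produces_no_movement(self, clean_profiles,
                                                    complete_model):
        rest = gen_rest(2000, noise_sd=0.0, seed=0)
        spiked = inject_spike(rest, 500, 80, amplitude=1.5)
        run = run_controller(spiked, complete_model,
                             ControllerConfig(mode="COMPLETE"), HandSim())
        assert run.executed == []

    def test_sub_100ms_spike_leaves_executed_unchanged(self, clean_profiles,
                                                       complete_model):
        for width in (20, 60, 98):
            stream, intended = gen_session(clean_profiles, reps=1, seed=3)
            # inside the first rest segment (3000-6000 ms)
            spiked = inject_spike(stream, 4000, width, amplitude=1.5)
            cfg = ControllerConfig(mode="COMPLETE")
            base = run_controller(stream, complete_model, cfg, HandSim())
            with_spike = run_controller(spiked, complete_model, cfg, HandSim())
            assert with_spike.executed_labels == base.executed_labels

    def test_alternation_invariant(self, noisy_profiles, complete_model):
        _, _, run = run_session(noisy_profiles, complete_model, "COMPLETE",
                                reps=3, seed=5)
        non_open_streak = 0
        for g in run.executed_labels:
            if g is OPEN:
                non_open_streak = 0
            else:
                non_open_streak += 1
                assert non_open_streak <= 1

    def test_holding_requires_no_contraction(self, clean_profiles,
                                             complete_model):
        # actuate a grasp, then feed a long rest stream: the hand holds
        contraction = gen_contraction(
            [p for p in clean_profiles if p.label is POWER][0], 3000, seed=0)
        rest = gen_rest(10_000, noise_sd=0.0, seed=0)
        stream = concat_streams([contraction, rest])
        run = run_controller(stream, complete_model,
                             ControllerConfig(mode="COMPLETE"), HandSim())
        assert run.executed_labels == [POWER]
        assert run.hand.hand_position is POWER

    def test_complete_ignores_non_open_while_holding(self, clean_profiles,
                                                     complete_model):
        pmap = {p.label: p for p in clean_profiles}
        stream = concat_streams([
            gen_contraction(pmap[POWER], 3000, seed=0),
            gen_rest(3000, 0.0, 0),
            gen_contraction(pmap[PRECISION], 3000, seed=0),  # ignored: holding
            gen_rest(3000, 0.0, 0),
            gen_contraction(pmap[OPEN], 3000, seed=0),       # reset
            gen_rest(3000, 0.0, 0),
        ])
        run = run_controller(stream, complete_model,
                             ControllerConfig(mode="COMPLETE"), HandSim())
        assert run.executed_labels == [POWER, OPEN]
        assert any(e == "held:ignored_non_open" for _, e in run.events)

    def test_reduced_resets_on_any_contraction(self, clean_profiles,
                                               reduced_model):
        pmap = {p.label: p for p in clean_profiles}
        stream = concat_streams([
            gen_contraction(pmap[POINT], 3000, seed=0),
            gen_rest(3000, 0.0, 0),
            gen_contraction(pmap[POWER], 3000, seed=0),  # any contraction
            gen_rest(3000, 0.0, 0),
        ])
        run = run_controller(stream, reduced_model,
                             ControllerConfig(mode="REDUCED"), HandSim())
        assert run.executed_labels == [POINT, OPEN]

    def test_complete_and_reduced_execute_identically_on_noiseless(
            self, clean_profiles, complete_model, reduced_model):
        stream, intended = gen_session(clean_profiles, reps=2, seed=7)
        rc = run_controller(stream, complete_model,
                            ControllerConfig(mode="COMPLETE"), HandSim())
        rr = run_controller(stream, reduced_model,
                            ControllerConfig(mode="REDUCED"), HandSim())
        assert rc.executed_labels == rr.executed_labels == intended

    def test_trace_codes_follow_convention(self, clean_profiles,
                                           complete_model):
        _, _, run = run_session(clean_profiles, complete_model, "COMPLETE",
                                reps=1)
        for (_, code), (_, gesture) in zip(run.trace, run.executed):
            assert code == (-1 if gesture is OPEN else int(gesture))
            assert code == -1 or code > 0

    def test_mode_mismatch_rejected(self, complete_model, reduced_model):
        stream = gen_rest(100, seed=0)
        with pytest.raises(ValueError):
            run_controller(stream, complete_model,
                           ControllerConfig(mode="REDUCED"))
        with pytest.raises(ValueError):
            run_controller(stream, reduced_model,
                           ControllerConfig(mode="COMPLETE"))

    def test_vote_buffer_bounded_by_window(self, clean_profiles,
                                           complete_model):
        stream, _ = gen_session(clean_profiles, reps=1, seed=1)
        cfg = ControllerConfig(mode="COMPLETE")
        # instrument via events: every voting_start is followed by exactly
        # one decision, i.e. the buffer never grows past the window
        run = run_controller(stream, complete_model, cfg, HandSim())
        names = [e.split(":")[0] for _, e in run.events
                 if e.split(":")[0] in ("voting_start", "decision")]
        assert names == ["voting_start", "decision"] * (len(names) // 2)


class TestConfigValidation:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            ControllerConfig(activation_threshold=3.5)
        with pytest.raises(ValueError):
            ControllerConfig(decontraction_threshold=0.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ControllerConfig(mode="REDUCED", activation_threshold=0.35)
        path = tmp_path / "ctrl.yaml"
        cfg.to_yaml(path)
        assert ControllerConfig.from_yaml(path) == cfg
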