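"""Classification-mode control strategy of the prosthetic hand.

The wearable node drives the hand with a finite state machine layered on
top of the frame classifier:

* **ADC acquisition** — each 500 Hz frame is the mean of 16 consecutive
  ADC samples per channel.
* **Spike removal** — the onset trigger requires the activation measure to
  stay above the activation threshold for at least 100 ms (50 frames);
  shorter supra-threshold bursts are movement artifacts and are discarded.
* **SVM voting** — once triggered, every frame is classified and a
  majority vote over 20 consecutive classifications (40 ms) selects the
  gesture, suppressing transient misclassifications at the contraction
  onset.
* **Gesture configuration** — the decided gesture is actuated by the motor
  simulator; each finger stops on its current-feedback stall (fully open,
  fully closed, or blocked by a grasped object).  Because every gesture
  mechanically starts from the open hand, the FSM tracks the hand position
  without encoders: after an actuation the user may relax (the hand holds
  the grasp with no muscular effort) and the only reachable next position
  is the open-hand reset.

In REDUCED mode the reset needs no classification at all: any sustained
contraction while holding a gesture reopens the hand.  In COMPLETE mode
the contraction is classified and only an open-hand decision moves the
hand; other labels leave the grasp untouched.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import yaml

from .gestures import Gesture, output_code, validate_mode
from .svm import SvmModel, svm_predict
from .synth import ADC_SPAN_V, FRAME_MS, EmgStream


class FsmNode(enum.Enum):
    IDLE = "IDLE"
    ONSET_CHECK = "ONSET_CHECK"
    VOTING = "VOTING"
    ACTUATING = "ACTUATING"
    HOLDING = "HOLDING"
    RESETTING = "RESETTING"


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable parameters of the control strategy.

    ``activation_threshold``/``decontraction_threshold`` form a hysteresis
    pair (defaults 0.3 V / 0.2 V) on the per-frame activation measure;
    ``spike_min_duration_ms`` must map to an integer frame count at the
    500 Hz frame rate (100 ms -> 50 frames).
    """

    activation_threshold: float = 0.3
    decontraction_threshold: float = 0.2
    spike_min_duration_ms: float = 100.0
    vote_window: int = 20
    frame_rate: int = 500
    adc_oversample: int = 16
    mode: str = "COMPLETE"
    activation_measure: str = "max"  # max | mean | sum of channels

    def __post_init__(self):
        for name in ("activation_threshold", "decontraction_threshold"):
            v = getattr(self, name)
            if not 0 < v < ADC_SPAN_V:
                raise ValueError(f"{name} must lie in (0, {ADC_SPAN_V}) V")
        if self.vote_window < 1:
            raise ValueError("vote_window must be >= 1")
        frames = self.spike_min_duration_ms * self.frame_rate / 1000.0
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError(
                "spike_min_duration_ms must be an integer number of frames"
            )
        validate_mode(self.mode)
        if self.activation_measure not in ("max", "mean", "sum"):
            raise ValueError("activation_measure must be max, mean or sum")

    @property
    def spike_frames(self) -> int:
        """Frames the signal must stay above threshold to count as an onset."""
        return int(round(self.spike_min_duration_ms * self.frame_rate / 1000.0))

    def activation(self, channels) -> float:
        c = np.asarray(channels, dtype=float)
        if self.activation_measure == "max":
            return float(c.max())
        if self.activation_measure == "mean":
            return float(c.mean())
        return float(c.sum())

    @classmethod
    def from_yaml(cls, path) -> "ControllerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Simulated poliarticulated hand

FINGERS = ("thumb", "index", "middle", "ring", "little")

#: Per-gesture finger targets (0 = fully open, 1 = fully closed).
GESTURE_TARGETS = {
    Gesture.OPEN_HAND: dict.fromkeys(FINGERS, 0.0),
    Gesture.POWER_GRASP: dict.fromkeys(FINGERS, 1.0),
    # precision grasp: only thumb and index receive the closing command
    Gesture.PRECISION_GRASP: {**dict.fromkeys(FINGERS, 0.0),
                              "thumb": 1.0, "index": 1.0},
    # point index: every finger closes except the extended index
    Gesture.POINT_INDEX: {**dict.fromkeys(FINGERS, 1.0), "index": 0.0},
}


@dataclass
class HandSim:
    """Kinematic/current model of the poliarticulated hand.

    Each finger moves at constant speed toward its commanded position and
    its DC motor stops on the current-feedback stall: when the finger is
    fully open, fully closed, or halted by a grasped object, the drawn
    current jumps past ``stall_threshold`` and the H-bridge feedback cuts
    the drive.  ``object_width`` (if set) blocks closing fingers at that
    position, modelling a grasped object.
    """

    finger_position: dict = field(
        default_factory=lambda: dict.fromkeys(FINGERS, 0.0))
    motor_current: dict = field(
        default_factory=lambda: dict.fromkeys(FINGERS, 0.0))
    stall_threshold: float = 0.8   # amperes
    idle_current: float = 0.15     # amperes while moving freely
    stall_current: float = 1.2     # amperes at the stop transient
    speed: float = 1.0 / 300.0     # full travel in 300 ms
    object_width: float | None = None
    hand_position: Gesture = Gesture.OPEN_HAND

    @property
    def is_open(self) -> bool:
        return all(p == 0.0 for p in self.finger_position.values())

    def actuate(self, gesture: Gesture) -> float:
        """Execute a gesture; returns the simulated motor time in ms.

        Non-open gestures require the hand to be in the open (reset)
        position — the FSM guarantees this; calling around it is an error.
        """
        gesture = Gesture(gesture)
        if gesture is not Gesture.OPEN_HAND and not self.is_open:
            raise RuntimeError(
                "mechanical constraint violated: gestures start from the "
                "open-hand reset position"
            )
        targets = GESTURE_TARGETS[gesture]
        duration = 0.0
        for f in FINGERS:
            start = self.finger_position[f]
            target = targets[f]
            if self.object_width is not None and target > start:
                # an object blocks closing fingers at its width
                target = min(target, max(self.object_width, start))
            travel = abs(target - start)
            if travel > 0:
                duration = max(duration, travel / self.speed)
            self.finger_position[f] = target
            # at the stop the motor stalls above threshold, then is cut off
            self.motor_current[f] = self.stall_current if travel > 0 else 0.0
        for f in FINGERS:
            if self.motor_current[f] > self.stall_threshold:
                self.motor_current[f] = 0.0  # H-bridge feedback stop
        self.hand_position = gesture
        return duration


def actuate(hand: HandSim, gesture: Gesture) -> HandSim:
    """Functional wrapper over :meth:`HandSim.actuate` (returns the hand)."""
    hand.actuate(gesture)
    return hand


# ---------------------------------------------------------------------------
# FSM state and elementary steps


@dataclass
class ControllerState:
    node: FsmNode = FsmNode.IDLE
    above_threshold_frames: int = 0
    vote_buffer: list = field(default_factory=list)
    hand_position: Gesture = Gesture.OPEN_HAND
    awaiting_decontraction: bool = False
    output_trace: list = field(default_factory=list)   # (t_ms, code)
    events: list = field(default_factory=list)         # (t_ms, name)


def acquire_frame(raw, adc_oversample: int = 16) -> np.ndarray:
    """ADC acquisition: per-channel mean of the 16 consecutive samples."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != adc_oversample:
        raise ValueError(
            f"expected {adc_oversample} x NF raw samples, got shape {raw.shape}"
        )
    return raw.mean(axis=0)


def majority_vote(labels) -> Gesture:
    """Most frequent label; ties resolve to the lowest class index."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot vote on an empty label list")
    counts = Counter(Gesture(l) for l in labels)
    best = max(counts.values())
    return min(g for g, c in counts.items() if c == best)


def spike_filter_step(state: ControllerState, frame,
                      config: ControllerConfig) -> ControllerState:
    """One spike-removal step (IDLE/ONSET_CHECK nodes).

    Counts consecutive supra-threshold frames; a drop below the activation
    threshold before 100 ms discards the burst as an artifact, reaching the
    100 ms mark (boundary inclusive) arms the classifier.
    """
    if state.node not in (FsmNode.IDLE, FsmNode.ONSET_CHECK):
        raise ValueError("spike filter runs only in IDLE/ONSET_CHECK")
    if config.activation(frame) >= config.activation_threshold:
        state.above_threshold_frames += 1
        state.node = FsmNode.ONSET_CHECK
        if state.above_threshold_frames >= config.spike_frames:
            state.node = FsmNode.VOTING
            state.vote_buffer = []
    else:
        state.above_threshold_frames = 0
        state.node = FsmNode.IDLE
    return state


def voting_step(state: ControllerState, channels, model: SvmModel,
                config: ControllerConfig) -> "Gesture | None":
    """One SVM-voting step; returns the decided gesture once the window fills."""
    if state.node is not FsmNode.VOTING:
        raise ValueError("voting step requires the VOTING node")
    state.vote_buffer.append(svm_predict(channels, model))
    if len(state.vote_buffer) >= config.vote_window:
        decided = majority_vote(state.vote_buffer)
        state.vote_buffer = []
        return decided
    return None


@dataclass
class RunResult:
    """Outcome of a full controller pass over a stream."""

    executed: list          # (t_ms, Gesture) actuated movements, resets included
    trace: list             # (t_ms, code): -1 reset, positive = gesture
    events: list            # (t_ms, event name) diagnostic log
    state: ControllerState
    hand: HandSim

    @property
    def executed_labels(self) -> list:
        return [g for _, g in self.executed]


def check_mode_match(model: SvmModel, config: ControllerConfig) -> None:
    has_open = Gesture.OPEN_HAND in model.class_labels
    if config.mode == "REDUCED" and has_open:
        raise ValueError("REDUCED controller requires a model without OPEN_HAND")
    if config.mode == "COMPLETE" and not has_open:
        raise ValueError("COMPLETE controller requires a model including OPEN_HAND")


def run_controller(stream: EmgStream, model: SvmModel,
                   config: ControllerConfig | None = None,
                   hand: HandSim | None = None) -> RunResult:
    """Run the full classification-mode FSM over an envelope stream.

    Returns every executed movement (gestures and resets) with its
    actuation time, the output trace in the -1/positive code convention,
    and a diagnostic event log (voting_start, decision, decontraction, ...).
    """
    config = config or ControllerConfig()
    check_mode_match(model, config)
    if stream.n_channels != model.n_features:
        raise ValueError(
            f"stream has {stream.n_channels} channels, model expects "
            f"{model.n_features}"
        )
    hand = hand or HandSim()
    st = ControllerState(hand_position=hand.hand_position)
    reduced = config.mode == "REDUCED"
    act_thr = config.activation_threshold
    dec_thr = config.decontraction_threshold
    spike_frames = config.spike_frames

    # vectorised activation measure over the whole stream
    if config.activation_measure == "max":
        activation = stream.channels.max(axis=1)
    elif config.activation_measure == "mean":
        activation = stream.channels.mean(axis=1)
    else:
        activation = stream.channels.sum(axis=1)

    def do_actuate(t, gesture):
        node_before = FsmNode.RESETTING if gesture is Gesture.OPEN_HAND else FsmNode.ACTUATING
        st.node = node_before
        hand.actuate(gesture)
        st.hand_position = gesture
        executed.append((t, gesture))
        st.output_trace.append((t, output_code(gesture)))
        st.events.append((t, f"actuated:{gesture.name}"))

    executed = []
    for i in range(len(stream)):
        t = float(stream.t_ms[i])
        a = float(activation[i])

        if st.awaiting_decontraction:
            if a < dec_thr:
                st.awaiting_decontraction = False
                st.events.append((t, "decontraction"))
                st.node = FsmNode.IDLE if st.hand_position is Gesture.OPEN_HAND \
                    else FsmNode.HOLDING
            continue

        if st.node in (FsmNode.IDLE, FsmNode.HOLDING):
            if a >= act_thr:
                st.above_threshold_frames = 1
                st.node = FsmNode.ONSET_CHECK
            continue

        if st.node is FsmNode.ONSET_CHECK:
            if a >= act_thr:
                st.above_threshold_frames += 1
                if st.above_threshold_frames >= spike_frames:
                    st.above_threshold_frames = 0
                    holding = st.hand_position is not Gesture.OPEN_HAND
                    if holding and reduced:
                        # any sustained contraction while holding reopens
                        do_actuate(t, Gesture.OPEN_HAND)
                        st.node = FsmNode.IDLE
                        st.awaiting_decontraction = True
                    else:
                        st.node = FsmNode.VOTING
                        st.vote_buffer = []
                        st.events.append((t, "voting_start"))
            else:
                st.above_threshold_frames = 0
                st.node = FsmNode.IDLE if st.hand_position is Gesture.OPEN_HAND \
                    else FsmNode.HOLDING
            continue

        if st.node is FsmNode.VOTING:
            decided = voting_step(st, stream.channels[i], model, config)
            if decided is None:
                continue
            st.events.append((t, f"decision:{decided.name}"))
            holding = st.hand_position is not Gesture.OPEN_HAND
            if holding:
                # only the open-hand reset can move a holding hand
                if decided is Gesture.OPEN_HAND:
                    do_actuate(t, Gesture.OPEN_HAND)
                    st.node = FsmNode.IDLE
                else:
                    st.events.append((t, "held:ignored_non_open"))
                    st.node = FsmNode.HOLDING
            else:
                if decided is Gesture.OPEN_HAND:
                    # hand already open: nothing to actuate
                    st.events.append((t, "open_while_open:ignored"))
                    st.node = FsmNode.IDLE
                else:
                    do_actuate(t, decided)
                    st.node = FsmNode.HOLDING
            st.awaiting_decontraction = True
            continue

    return RunResult(executed=executed, trace=st.output_trace,
                     events=st.events, state=st, hand=hand)
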