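"""Synthetic multi-channel EMG-envelope generator.

Active prosthetic EMG sensors (e.g. the Ottobock 13E200 family) rectify,
filter and integrate the raw myoelectric signal in hardware, so the signal
reaching the controller's ADC is a slowly varying non-negative *envelope*
per channel, bounded by the 0-3.3 V ADC span and sampled at 500 Hz.  This
module synthesises labeled envelope streams with the features the
controller has to cope with:

* gesture-specific steady-state channel activation patterns,
* an onset transient (raised-cosine ramp) from rest to the contraction,
* a small positive rest baseline,
* additive Gaussian noise clipped to the ADC span,
* spurious short supra-threshold spikes (movement artifacts).

The experimental protocol it emulates alternates 3 s contractions with 3 s
of rest, and interleaves an open-hand (reset) movement after every gesture,
so a session of R repetitions of G gestures contains ``R * G * 2`` intended
movements.

All generators are deterministic given their ``seed`` argument; no global
RNG state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gestures import Gesture, REST, parse_label, validate_mode

#: Sampling rate of the acquisition front-end (Hz).
SAMPLE_RATE_HZ = 500
#: Frame period in milliseconds.
FRAME_MS = 1000.0 / SAMPLE_RATE_HZ
#: ADC input span (volts).
ADC_SPAN_V = 3.3
#: Number of EMG channels / input features of the deployed armband.
N_CHANNELS = 4
#: Rest-level envelope baseline (volts).  Active sensors output a small
#: positive offset even on a relaxed muscle.
REST_BASELINE_V = 0.05
#: Default additive envelope noise (volts, standard deviation).
DEFAULT_NOISE_SD = 0.08
#: Default onset transient duration (ms).
DEFAULT_RISE_MS = 200.0
#: Protocol timing: contraction and rest segment durations (ms).
CONTRACTION_MS = 3000.0
REST_MS = 3000.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def n_frames(duration_ms: float) -> int:
    """Number of 500 Hz frames in a duration (round to nearest)."""
    return int(round(duration_ms / FRAME_MS))


@dataclass(frozen=True)
class GestureProfile:
    """Steady-state activation pattern of one gesture.

    Parameters
    ----------
    label
        The gesture this profile generates.
    mean_activation
        Per-channel steady-state envelope level in volts; length defines
        the number of channels and every entry must lie in the ADC span.
    rise_time_ms
        Duration of the raised-cosine onset transient.
    noise_sd
        Standard deviation of the additive Gaussian envelope noise (volts).
    """

    label: Gesture
    mean_activation: tuple
    rise_time_ms: float = DEFAULT_RISE_MS
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self):
        act = np.asarray(self.mean_activation, dtype=float)
        if act.ndim != 1 or act.size == 0:
            raise ValueError("mean_activation must be a non-empty vector")
        if np.any(act < 0) or np.any(act > ADC_SPAN_V):
            raise ValueError(
                f"mean_activation must lie within [0, {ADC_SPAN_V}] V"
            )
        if self.rise_time_ms < 0:
            raise ValueError("rise_time_ms must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "mean_activation", tuple(float(a) for a in act))

    @property
    def n_channels(self) -> int:
        return len(self.mean_activation)


@dataclass
class EmgStream:
    """A time-ordered sequence of envelope frames with optional labels.

    ``channels`` has shape ``(n, nf)``; ``t_ms[i]`` advances in 2 ms steps
    at the fixed 500 Hz rate.  ``labels`` (if present) holds one
    :class:`Gesture` or :data:`REST` per frame.
    """

    t_ms: np.ndarray
    channels: np.ndarray
    labels: list | None = None

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if len(self.t_ms) != len(self.channels):
            raise ValueError("t_ms and channels lengths differ")
        if self.labels is not None and len(self.labels) != len(self.channels):
            raise ValueError("labels length differs from frames")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    def frame(self, i: int):
        """(t_ms, channel vector) of frame *i*."""
        return self.t_ms[i], self.channels[i]

    def copy(self) -> "EmgStream":
        return EmgStream(
            self.t_ms.copy(),
            self.channels.copy(),
            None if self.labels is None else list(self.labels),
        )


def concat_streams(streams) -> EmgStream:
    """Concatenate streams, re-stamping time contiguously at 500 Hz."""
    streams = list(streams)
    if not streams:
        raise ValueError("no streams to concatenate")
    channels = np.concatenate([s.channels for s in streams])
    labels = None
    if all(s.labels is not None for s in streams):
        labels = [lab for s in streams for lab in s.labels]
    t = np.arange(len(channels)) * FRAME_MS
    return EmgStream(t, channels, labels)


def _finalize(values: np.ndarray) -> np.ndarray:
    return np.clip(values, 0.0, ADC_SPAN_V)


def gen_contraction(profile: GestureProfile, duration_ms: float, seed=0) -> EmgStream:
    """Generate one labeled muscular contraction.

    Channels ramp from the rest baseline to ``profile.mean_activation``
    along a raised-cosine transient of ``rise_time_ms``, then hold at the
    plateau; zero-mean Gaussian noise is added throughout and the result is
    clipped to the ADC span.  Every frame is labeled with the profile's
    gesture.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = _rng(seed)
    n = n_frames(duration_ms)
    t = np.arange(n) * FRAME_MS
    peak = np.asarray(profile.mean_activation)
    if profile.rise_time_ms > 0:
        frac = np.minimum(t / profile.rise_time_ms, 1.0)
        ramp = 0.5 * (1.0 - np.cos(np.pi * frac))
    else:
        ramp = np.ones(n)
    mean = REST_BASELINE_V + ramp[:, None] * (peak[None, :] - REST_BASELINE_V)
    noise = rng.normal(0.0, profile.noise_sd, size=mean.shape) if profile.noise_sd else 0.0
    return EmgStream(t, _finalize(mean + noise), [profile.label] * n)


def gen_rest(duration_ms: float, noise_sd: float = DEFAULT_NOISE_SD, seed=0,
             n_channels: int = N_CHANNELS,
             baseline: float = REST_BASELINE_V) -> EmgStream:
    """Generate a relaxed-muscle segment labeled :data:`REST`."""
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = _rng(seed)
    n = n_frames(duration_ms)
    t = np.arange(n) * FRAME_MS
    mean = np.full((n, n_channels), baseline)
    noise = rng.normal(0.0, noise_sd, size=mean.shape) if noise_sd else 0.0
    return EmgStream(t, _finalize(mean + noise), [REST] * n)


def inject_spike(stream: EmgStream, at_ms: float, width_ms: float,
                 amplitude: float, seed=0) -> EmgStream:
    """Superimpose a short supra-threshold burst on all channels.

    Models a movement artifact: a rectangular burst of ``amplitude`` volts
    added to every channel over ``[at_ms, at_ms + width_ms)``.  Labels are
    left untouched (artifacts are not gestures).  The burst is
    deterministic; ``seed`` is reserved for randomized spike shapes.
    """
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    t0, t1 = stream.t_ms[0], stream.t_ms[-1] + FRAME_MS
    if at_ms < t0 or at_ms + width_ms > t1:
        raise ValueError("spike interval lies outside the stream")
    out = stream.copy()
    mask = (out.t_ms >= at_ms) & (out.t_ms < at_ms + width_ms)
    out.channels[mask] = _finalize(out.channels[mask] + amplitude)
    return out


def default_profiles(noise_sd: float = DEFAULT_NOISE_SD,
                     rise_time_ms: float = DEFAULT_RISE_MS) -> list:
    """The built-in "healthy subject" activation patterns.

    Channel order mirrors the deployed armband: flexor carpi radialis,
    flexor carpi ulnaris, extensor digitorum communis, extensor carpi
    ulnaris.  Flexion-driven grasps load the first two channels, the open
    hand loads the extensors; the four vectors are channel-distinct so the
    classes are separable at low noise.
    """
    patterns = {
        Gesture.OPEN_HAND: (0.25, 0.30, 1.60, 1.40),
        Gesture.POWER_GRASP: (1.80, 1.70, 0.90, 0.80),
        Gesture.POINT_INDEX: (0.60, 1.40, 1.10, 0.40),
        Gesture.PRECISION_GRASP: (1.20, 0.50, 0.40, 1.00),
    }
    return [
        GestureProfile(label, act, rise_time_ms=rise_time_ms, noise_sd=noise_sd)
        for label, act in patterns.items()
    ]


def subject_profiles(seed: int, noise_sd: float = DEFAULT_NOISE_SD,
                     gain_jitter_sd: float = 0.05,
                     rise_time_ms: float = DEFAULT_RISE_MS) -> list:
    """Per-subject variant of :func:`default_profiles`.

    Emulates inter-subject variability (electrode placement, muscle bulk)
    as a multiplicative per-channel gain drawn once per subject from
    ``N(1, gain_jitter_sd)``, applied to every gesture's activation vector.
    """
    rng = _rng(seed)
    base = default_profiles(noise_sd=noise_sd, rise_time_ms=rise_time_ms)
    gains = np.clip(rng.normal(1.0, gain_jitter_sd, size=len(base[0].mean_activation)),
                    0.5, 1.5)
    out = []
    for p in base:
        act = np.clip(np.asarray(p.mean_activation) * gains, 0.0, ADC_SPAN_V)
        out.append(replace(p, mean_activation=tuple(act)))
    return out


def _profile_map(profiles) -> dict:
    m = {p.label: p for p in profiles}
    if len(m) != len(list(profiles)):
        raise ValueError("duplicate gesture profiles")
    return m


def gen_session(profiles, reps: int, mode: str = "COMPLETE", seed=0,
                contraction_ms: float = CONTRACTION_MS,
                rest_ms: float = REST_MS):
    """Generate one interleaved evaluation session.

    For each repetition of each non-open gesture the stream contains a
    contraction followed by rest, then an open-hand contraction (the
    interleaved reset) followed by rest.  With 10 repetitions of 3 gestures
    this yields the protocol's 60 consecutive movements.

    Returns ``(stream, intended)`` where ``intended`` lists every movement
    (resets included) in execution order.  The stream does not depend on
    ``mode``: the muscle activity a user produces is the same whichever
    model variant is deployed; ``mode`` is validated for interface
    consistency only.
    """
    validate_mode(mode)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pmap = _profile_map(profiles)
    if Gesture.OPEN_HAND not in pmap:
        raise ValueError("profiles must include OPEN_HAND for the interleaved resets")
    gestures = [p.label for p in profiles if p.label is not Gesture.OPEN_HAND]
    if not gestures:
        raise ValueError("profiles must include at least one non-open gesture")
    open_profile = pmap[Gesture.OPEN_HAND]
    rng = _rng(seed)
    segments, intended = [], []
    for _ in range(reps):
        for g in gestures:
            p = pmap[g]
            segments.append(gen_contraction(p, contraction_ms, rng))
            segments.append(gen_rest(rest_ms, p.noise_sd, rng, p.n_channels))
            intended.append(g)
            segments.append(gen_contraction(open_profile, contraction_ms, rng))
            segments.append(gen_rest(rest_ms, open_profile.noise_sd, rng,
                                     open_profile.n_channels))
            intended.append(Gesture.OPEN_HAND)
    return concat_streams(segments), intended


def gen_training_set(profiles, reps_per_gesture: int, mode: str = "COMPLETE",
                     seed=0, contraction_ms: float = CONTRACTION_MS,
                     stride: int = 10):
    """Generate labeled steady-state training samples.

    For every profile, ``reps_per_gesture`` contractions are generated and
    only plateau frames (after the onset transient) are kept, subsampled
    with ``stride`` (adjacent 500 Hz envelope frames are strongly
    autocorrelated, so a 20 ms stride loses no information while keeping
    the margin optimization cheap).  REST frames are never included; in
    REDUCED mode the open-hand gesture is excluded entirely, since the
    control strategy does not need to classify the reset movement.

    Returns ``(X, y)``: feature matrix ``(n, nf)`` and integer gesture
    labels.
    """
    mode = validate_mode(mode)
    if reps_per_gesture < 1:
        raise ValueError("reps_per_gesture must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rng = _rng(seed)
    use = [p for p in profiles
           if not (mode == "REDUCED" and p.label is Gesture.OPEN_HAND)]
    if not use:
        raise ValueError("no profiles left to train on")
    xs, ys = [], []
    for p in use:
        start = n_frames(p.rise_time_ms)
        for _ in range(reps_per_gesture):
            c = gen_contraction(p, contraction_ms, rng)
            plateau = c.channels[start::stride] if start < len(c) else c.channels[:0]
            xs.append(plateau)
            ys.extend([int(p.label)] * len(plateau))
    return np.concatenate(xs), np.asarray(ys, dtype=int)


def plateau_frames_per_contraction(profile: GestureProfile,
                                   contraction_ms: float = CONTRACTION_MS,
                                   stride: int = 10) -> int:
    """Number of training samples one contraction contributes."""
    total = n_frames(contraction_ms)
    start = n_frames(profile.rise_time_ms)
    return len(range(start, total, stride)) if start < total else 0


# ---------------------------------------------------------------------------
# CSV session dialect: header  t_ms,ch1..chN,label  (label = gesture name or
# REST); round-trips losslessly to 6 significant digits.

def write_csv(stream: EmgStream, path) -> None:
    nf = stream.n_channels
    cols = {"t_ms": stream.t_ms}
    for j in range(nf):
        cols[f"ch{j + 1}"] = stream.channels[:, j]
    if stream.labels is not None:
        cols["label"] = [
            lab if isinstance(lab, str) else lab.name for lab in stream.labels
        ]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def read_csv(path) -> EmgStream:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is rich
        raise ValueError(f"cannot parse session CSV {path}: {exc}") from exc
    if "t_ms" not in df.columns:
        raise ValueError(f"{path}: missing t_ms column")
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if not ch_cols:
        raise ValueError(f"{path}: no channel columns (ch1..chN)")
    ch_cols.sort(key=lambda c: int(c[2:]))
    if df[ch_cols].isna().any().any():
        bad = int(df[ch_cols].isna().any(axis=1).idxmax()) + 2  # header line = 1
        raise ValueError(f"{path}: malformed channel value at line {bad}")
    labels = None
    if "label" in df.columns:
        labels = [parse_label(str(v)) for v in df["label"]]
    return EmgStream(df["t_ms"].to_numpy(), df[ch_cols].to_numpy(), labels)
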