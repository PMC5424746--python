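"""End-to-end evaluation of the gesture controller.

Offline EMG studies report per-sample classification accuracy, but a
prosthesis needs exactly one correct, timely decision per movement.  The
metric used here is therefore gesture-level: over an interleaved session
(each gesture followed by an open-hand reset, 10 repetitions of 3 gestures
= 60 consecutive movements), the *end-to-end error rate* is the fraction
of intended movements the controller failed to execute correctly — one
error in 10 movements is a 10% error rate, one in 60 is 1.66% (98.4%
accuracy).

The module also provides stratified k-fold cross-validation of the
sample-level classifier, the paired COMPLETE/REDUCED experiment that
mirrors one subject row of the deployed system's evaluation, and a CSV
replay path for external recordings (any channel count, e.g. 10-sensor
benchmark datasets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .controller import ControllerConfig, HandSim, run_controller
from .gestures import Gesture, REST, validate_mode
from .svm import EmbeddedSVC, SvmModel, model_footprint_bytes, svm_predict_batch
from . import synth


@dataclass
class SessionResult:
    """Intended-vs-executed outcome of one session."""

    intended: list
    executed: list
    fsm_errors: int
    error_rate_pct: float
    accuracy_pct: float


@dataclass
class ModelReport:
    """Summary of one trained model variant."""

    mode: str
    n_classes: int
    n_sv: int
    footprint_bytes: int
    cv_accuracy_pct: float  # NaN when cross-validation was skipped


def truncate_pct(value: float, decimals: int = 2) -> float:
    """Truncate (not round) a percentage to the printed precision."""
    factor = 10 ** decimals
    return math.floor(value * factor) / factor


def end_to_end_error(intended, executed) -> SessionResult:
    """Score executed movements against the intended sequence.

    Movements are matched positionally in order of actuation; a wrong
    gesture counts as one error and a missed (or spurious extra) movement
    counts as one error each.  ``executed`` accepts either labels or the
    controller's ``(t_ms, label)`` pairs.
    """
    intended = [Gesture(g) for g in intended]
    if not intended:
        raise ValueError("intended movement list is empty")
    executed = [Gesture(e[1]) if isinstance(e, tuple) else Gesture(e)
                for e in executed]
    n, m = len(intended), len(executed)
    errors = sum(1 for a, b in zip(intended, executed) if a != b) + abs(n - m)
    rate = 100.0 * errors / n
    return SessionResult(intended, executed, errors, rate, 100.0 - rate)


def cross_val_accuracy(X, y, k: int = 5, seed: int = 0, gamma="scale_nf",
                       c: float = 1.0) -> float:
    """Stratified k-fold per-sample accuracy of the packed classifier (%).

    Folds are stratified by gesture; held-out frames are classified with
    the packed prediction path of the trained model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = total = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = EmbeddedSVC(c=c, gamma=gamma).fit(X[train_idx], y[train_idx])
        pred = np.asarray([int(g) for g in
                           svm_predict_batch(X[test_idx], clf.model_)])
        correct += int((pred == y[test_idx]).sum())
        total += len(test_idx)
    return 100.0 * correct / total


def intended_from_labels(stream: synth.EmgStream) -> list:
    """Recover the intended movement sequence from per-frame labels.

    Consecutive runs of the same non-REST label form one intended
    movement, resets included.
    """
    if stream.labels is None:
        raise ValueError("stream carries no labels")
    intended, prev = [], REST
    for lab in stream.labels:
        if lab != prev and lab != REST:
            intended.append(Gesture(lab))
        prev = lab
    return intended


@dataclass
class ExperimentResult:
    """Paired COMPLETE/REDUCED outcome for one synthetic subject."""

    reports: dict      # mode -> ModelReport
    sessions: dict     # mode -> SessionResult
    seed: int


def _train(X, y, mode, gamma, c):
    return EmbeddedSVC(c=c, gamma=gamma, mode=mode).fit(X, y).model_


def run_subject_session(seed: int, mode: str = "REDUCED",
                        noise_sd: float = synth.DEFAULT_NOISE_SD,
                        reps: int = 10, train_reps: int = 4,
                        gamma="scale_nf", c: float = 1.0,
                        config: ControllerConfig | None = None):
    """Train one model variant for one synthetic subject and run a session.

    Returns ``(SessionResult, SvmModel)``.  The subject's activation
    profiles carry a seed-specific per-channel gain, emulating
    inter-subject variability.
    """
    mode = validate_mode(mode)
    profiles = synth.subject_profiles(seed, noise_sd=noise_sd)
    X, y = synth.gen_training_set(profiles, train_reps, mode=mode, seed=seed)
    model = _train(X, y, mode, gamma, c)
    stream, intended = synth.gen_session(profiles, reps=reps, mode=mode,
                                         seed=seed + 1)
    cfg = config or ControllerConfig(mode=mode)
    run = run_controller(stream, model, cfg, HandSim())
    return end_to_end_error(intended, run.executed), model


def mean_end_to_end_error(n_subjects: int = 20, base_seed: int = 1,
                          mode: str = "REDUCED",
                          noise_sd: float = synth.DEFAULT_NOISE_SD,
                          reps: int = 10, train_reps: int = 4) -> float:
    """Mean session error rate (%) over independently seeded subjects."""
    rates = []
    for s in range(n_subjects):
        result, _ = run_subject_session(base_seed + 1000 * s, mode=mode,
                                        noise_sd=noise_sd, reps=reps,
                                        train_reps=train_reps)
        rates.append(result.error_rate_pct)
    return float(np.mean(rates))


def run_experiment(seed: int, noise_sd: float = synth.DEFAULT_NOISE_SD,
                   reps: int = 10, train_reps: int = 4, gamma="scale_nf",
                   c: float = 1.0, cv_folds: int = 5) -> ExperimentResult:
    """One synthetic subject, evaluated in both controller modes.

    Generates the subject's training data and a single interleaved
    session, trains COMPLETE and REDUCED models, runs the controller in
    each mode on the *same* stream and reports per-mode model size,
    footprint, cross-validation accuracy (``cv_folds=0`` skips it) and the
    end-to-end session result — the synthetic analogue of one subject row
    of the deployed system's evaluation table.
    """
    profiles = synth.subject_profiles(seed, noise_sd=noise_sd)
    stream, intended = synth.gen_session(profiles, reps=reps, seed=seed + 1)
    reports, sessions = {}, {}
    for mode in ("COMPLETE", "REDUCED"):
        X, y = synth.gen_training_set(profiles, train_reps, mode=mode, seed=seed)
        model = _train(X, y, mode, gamma, c)
        cv = (cross_val_accuracy(X, y, k=cv_folds, seed=seed, gamma=gamma, c=c)
              if cv_folds else float("nan"))
        cfg = ControllerConfig(mode=mode)
        run = run_controller(stream, model, cfg, HandSim())
        reports[mode] = ModelReport(mode, model.n_classes, model.n_sv,
                                    model_footprint_bytes(model, 4), cv)
        sessions[mode] = end_to_end_error(intended, run.executed)
    return ExperimentResult(reports, sessions, seed)


def replay_csv(session_csv, model: SvmModel,
               config: ControllerConfig | None = None,
               intended=None) -> SessionResult:
    """Replay a recorded session CSV through the controller.

    Semantics are identical to :func:`run_controller` followed by
    :func:`end_to_end_error`.  ``intended`` defaults to the movement
    sequence recovered from the CSV's label column; unlabeled files must
    pass it explicitly.  Works for any channel count matching the model
    (e.g. 10-channel benchmark recordings with a 10-feature model).
    """
    stream = synth.read_csv(session_csv)
    if stream.n_channels != model.n_features:
        raise ValueError(
            f"CSV has {stream.n_channels} channels but the model expects "
            f"{model.n_features}"
        )
    if intended is None:
        intended = intended_from_labels(stream)
    config = config or ControllerConfig(
        mode="REDUCED" if Gesture.OPEN_HAND not in model.class_labels
        else "COMPLETE")
    run = run_controller(stream, model, config, HandSim())
    return end_to_end_error(intended, run.executed)
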