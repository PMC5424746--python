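# Methods

## System model

The package simulates a body-area prosthetic-hand controller as four
interacting components: an EMG-envelope source, a frame classifier, a
finite-state-machine (FSM) control strategy, and a model-update link. The
simulation is sample-accurate at the acquisition rate (500 Hz, 2 ms frames)
but event-based above it: motor motion is resolved analytically rather than
co-simulated, since only its completion (the current-feedback stall) gates
the FSM.

### Signal model

Active prosthetic EMG sensors deliver a rectified, low-pass-filtered,
integrated *envelope* per channel, so no feature extraction precedes
classification; the classifier input is the raw NF-dimensional envelope
vector (NF = 4 by default). The generator models one channel during a
contraction as

    v(t) = b + r(t) · (a_g − b) + ε(t),   ε(t) ~ N(0, σ²) i.i.d.,

clipped to the 0–3.3 V ADC span, where `b` is the rest baseline, `a_g` the
gesture's steady-state activation on that channel, and `r(t)` a raised-cosine
ramp over the onset transient. Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `SAMPLE_RATE_HZ` | 500 Hz | acquisition rate; one frame = mean of 16 ADC samples |
| `REST_BASELINE_V` | 0.05 V | relaxed-muscle envelope level |
| `noise_sd` (σ) | 0.08 V | additive envelope noise, per channel |
| `rise_time_ms` | 200 ms | onset transient duration |
| `mean_activation` | 0.25–1.8 V | per-gesture channel pattern (see below) |

The four built-in activation patterns assign each gesture a distinct channel
signature over (flexor carpi radialis, flexor carpi ulnaris, extensor
digitorum communis, extensor carpi ulnaris): the open hand loads the
extensors, the power grasp loads everything with flexor dominance, point
index and precision grasp each emphasise a different flexor/extensor mix.
The levels (≈0.25–1.8 V against a 3.3 V span) and the noise scale were fixed
once as a plausible healthy-subject regime: inter-class distances of ~1 V at
σ = 0.08 V make the classes well separated but not degenerate, which mirrors
the observation that healthy forearms produce cleanly separable patterns.
Per-subject variability is a multiplicative per-channel gain ~ N(1, 0.05²)
drawn once per subject seed.

What the generator does **not** model: raw (un-enveloped) EMG, the sensor's
integration dynamics (subsumed into the ramp), electrode shift, fatigue
drift, co-contraction crosstalk, and the degraded, overlapping patterns of
compromised residual muscles — the last is only approachable by raising
`noise_sd`. Passing tests therefore demonstrate the *control logic* under
its stated signal assumptions, not clinical performance: with i.i.d. noise
the 100 ms spike filter makes false triggers during rest essentially
impossible, which is optimistic for real movement artifacts (these are
correlated over tens of milliseconds; the `inject_spike` facility exists to
model exactly those).

### Classifier

One-vs-one soft-margin SVM with RBF kernel `exp(−γ‖x−s‖²)`. For a pair
(j, k), j < k, the decision value is `f(x) = Σ Cᵢ K(x, sᵢ) − ρ_jk` over the
two classes' support vectors with pre-computed `Cᵢ = yᵢαᵢ`; `f > 0` votes
for j, `f ≤ 0` for k (the boundary case is assigned to the second class,
consistent with strictly positive values belonging to the first). The
predicted class maximises the vote vector; ties take the lowest class index
(stable, and matching the common library convention). Vote totals always
sum to NCl(NCl−1)/2.

Margin optimization is delegated to libSVM through scikit-learn; the package
owns the packing. One subtlety found during verification: scikit-learn
negates the raw binary (2-class) libSVM decision so that positive values
mean `classes_[1]`, while its multiclass ovo decision values keep the raw
convention; the packer re-negates the binary coefficients and offset so the
packed layout has a single sign convention. The packed path accumulates in
double precision over single-precision stored values; its pair decisions
match the solver's to ~1e−6 relative, and predictions are checked (a) for
exact label agreement with an independently written brute-force evaluator on
randomized models, and (b) against the solver's own predictions wherever the
pairwise vote is untied (the solver breaks vote ties by summed confidences
instead of by index).

Hyperparameters: C = 1 and γ = 1/NF by default, overridable; no input
normalization is applied by default, since the classifier consumes bounded
voltages directly.

### Memory layout and footprint

The serialized model mirrors a static flash allocation: a fixed 20-byte
header (format tag, version, SVM type, NF, NCl, γ, NS), NCl 4-byte
(label, count) class entries, then the ρ block, the contiguous SV block and
the contiguous coefficient block, all little-endian IEEE-754 single
precision. Footprint in bytes is

    20 + d·(NS·NF + NS·(NCl−1) + NCl(NCl−1)/2) + 4·NCl,   d = 4 or 8,

and the serialized length equals the d = 4 value exactly. The largest
healthy-subject COMPLETE shape observed in practice (404 SVs, NF = 4,
NCl = 4) packs to 11.11 kB, inside a 12 kB flash budget.

### Control strategy

FSM nodes: IDLE → ONSET_CHECK → VOTING → ACTUATING/RESETTING → HOLDING.

* **Onset / spike removal** — the per-frame activation measure (maximum over
  channels by default; mean and sum are selectable) must stay at or above
  the activation threshold (0.3 V) for 100 ms = 50 consecutive frames;
  reaching the boundary triggers (≥, pinned for testability — one frame
  either way is physiologically irrelevant). Any shorter burst resets the
  counter, so sub-100 ms artifacts provably never change the executed
  sequence.
* **Voting** — every subsequent frame is classified regardless of threshold
  dips; after 20 consecutive classifications (one contiguous,
  non-overlapping window per onset) the majority label is the decision,
  40 ms after voting starts.
* **Actuation** — gestures may only be actuated from the open hand
  (mechanical reset constraint, enforced); each commanded finger moves at
  constant speed (full travel 300 ms) until fully open, fully closed, or
  blocked by the configured object width, at which point its motor current
  exceeds the stall threshold and the drive is cut. Output codes: positive
  integers for gestures, −1 for the reset.
* **Hold / reset** — after any actuation the controller waits for muscular
  decontraction (activation below 0.2 V; the 0.3/0.2 hysteresis pair
  prevents chatter — neither value is prescribed by the hardware, both are
  configurable) and then re-arms. While holding a grasp, a REDUCED
  controller re-opens on any sustained contraction without classifying it; a
  COMPLETE controller classifies and acts only on an open-hand decision,
  ignoring other labels (the hand cannot legally move anywhere else, so a
  non-open classification while holding is treated as noise, not an error).
  A classified open-hand while already open actuates nothing. Holding
  requires no muscle activity at all, which is the strategy's fatigue
  advantage.

### Transfer protocol

Model updates flow gateway → node as CONFIG, MODEL_PARAMS, then one packet
per SV, stop-and-wait: each packet carries a one-byte two's-complement sum
over type‖sequence‖payload (any single corrupted byte shifts the modular sum
and is detected; the checksum interface is pluggable should CRC-8 be
preferred), the node ACKs or NAKs, and the gateway retransmits on NAK up to
5 times before abandoning. ACKs are modeled as reliable. Field encodings
equal the file serialization, so a completed transfer is bit-identical to
the source model.

### Evaluation

The gesture-level metric aligns executed to intended movements positionally
in actuation order: a wrong gesture, a missed movement and a spurious extra
movement each count one error (misses are not distinguished from wrong
executions; the error rate can exceed 100% when spurious movements
dominate). `error_rate_pct = 100·errors/len(intended)` and
`accuracy_pct = 100 − error_rate_pct` exactly; percentages are reported at
full precision, with a truncation helper for two-decimal printed figures
(1/60 → 1.66). Cross-validation is stratified 5-fold by default (plain
k-fold would risk gesture-free folds at small rep counts); held-out frames
are scored through the packed predictor.

## Problem sizes

Default experiment sizes were chosen to keep a full run on one CPU core in
seconds while matching the session protocol: training uses 4 repetitions per
gesture with plateau frames subsampled at one per 20 ms (stride 10 —
adjacent 500 Hz envelope frames are nearly perfectly autocorrelated, so
denser sampling inflates fit cost without information), sessions are the
full 60 movements (360 s of signal, 180 000 frames), and the headline error
rate averages 20 subjects. The noise-monotonicity test uses shortened
sessions (2 repetitions) across 20 seeds and 3 noise levels.

## Known limitations

* The envelope model is phenomenological; no claim is made about raw-EMG
  realism, and amputee-grade pattern confusion is only a noise knob.
* The motor model resolves actuation analytically; actuation time does not
  consume stream time (the controller is event-driven during actuation on
  the real device as well, but concurrent EMG during motor motion is not
  simulated).
* sklearn's confidence-based vote tie-break cannot be reproduced bit-exactly
  by a pure vote argmax; ties are broken by lowest class index and the
  difference is confined to exactly tied vote vectors.
* The transfer simulation covers integrity and recovery, not timing, pairing
  or concurrent sessions.
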