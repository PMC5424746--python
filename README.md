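# emgctl — simulated wearable EMG prosthetic-hand controller

`emgctl` is a desk-scale software model of a myoelectric controller for a
poliarticulated prosthetic hand. Upper-limb prostheses are usually driven by
non-intuitive contraction codes; a more natural interface classifies the
wearer's surface-EMG activation pattern into hand gestures and actuates them
directly. Doing that on a low-cost microcontroller, robustly enough that
*whole movements* (not just individual samples) come out right, requires an
efficient classifier tightly integrated with a control strategy. This package
reproduces that full system in simulation, for researchers who want to study
or extend the control strategy without the hardware:

* **`emgctl.synth`** — a labeled 4-channel (or N-channel) EMG *envelope*
  generator at 500 Hz: gesture-specific activation patterns, raised-cosine
  onset transients, rest baseline, Gaussian noise clipped to the 0–3.3 V ADC
  span, and injectable movement-artifact spikes. Sessions follow the
  3 s-contraction / 3 s-rest protocol with an open-hand reset interleaved
  after every gesture (10 repetitions × 3 gestures → 60 movements).
* **`emgctl.svm`** — the embedded-style classifier. A one-vs-one SVM with RBF
  kernel K(x, s) = exp(−γ‖x−s‖²) classifies each envelope frame x ∈ ℝ^NF via
  the pairwise decision function

  f(x) = Σᵢ Cᵢ·K(x, sᵢ) − ρ,  Cᵢ = yᵢαᵢ,

  with the coefficients pre-computed at training time and every array packed
  into a static "flash image": a 20-byte header, per-class SV counts, the ρ
  block, then contiguous support-vector and coefficient blocks in
  little-endian single precision. Training (`EmbeddedSVC`, a scikit-learn
  estimator) delegates margin optimization to libSVM via scikit-learn and
  repacks the result; prediction runs the packed path. Models with the
  open-hand class are **COMPLETE**; **REDUCED** models drop it (the reset
  needs no classification) and are smaller and faster.
* **`emgctl.controller`** — the classification-mode finite state machine:
  16-sample ADC averaging, spike removal (supra-threshold bursts shorter than
  100 ms are artifacts and ignored), majority voting over 20 consecutive
  frame classifications (a decision every 40 ms), and gesture configuration
  with a simulated per-finger DC-motor current-feedback stop. The hand always
  starts a gesture from the open (reset) position, holds a grasp with no
  muscular effort, and re-opens on the next sustained contraction (REDUCED)
  or on a classified open-hand gesture (COMPLETE).
* **`emgctl.transfer`** — the gateway→node model-update protocol:
  CONFIG / MODEL_PARAMS / per-SV packets, one-byte checksums, stop-and-wait
  ACK/NAK with retransmission, over an injectable lossy channel.
* **`emgctl.evaluation`** — gesture-level metrics: the *end-to-end error
  rate* (fraction of intended movements, resets included, not executed
  correctly: 1 error in 10 movements = 10%, 1 in 60 = 1.66%), stratified
  k-fold cross-validation of the sample classifier, paired COMPLETE/REDUCED
  subject experiments, and CSV replay of external recordings.

## Worked example

```python
from emgctl.evaluation import run_experiment

exp = run_experiment(seed=1)   # one synthetic subject, both model variants
for mode in ("COMPLETE", "REDUCED"):
    rep, res = exp.reports[mode], exp.sessions[mode]
    print(f"{mode:9s} classes={rep.n_classes} SVs={rep.n_sv:3d} "
          f"footprint={rep.footprint_bytes} B  cv={rep.cv_accuracy_pct:.2f}%  "
          f"session: {res.fsm_errors}/{len(res.intended)} errors "
          f"({res.error_rate_pct:.2f}% error, {res.accuracy_pct:.2f}% accuracy)")
```

prints

```
COMPLETE  classes=4 SVs= 47 footprint=1376 B  cv=100.00%  session: 0/60 errors (0.00% error, 100.00% accuracy)
REDUCED   classes=3 SVs= 32 footprint=812 B  cv=100.00%  session: 0/60 errors (0.00% error, 100.00% accuracy)
```

One synthetic subject's training data (4 repetitions per gesture) trains both
model variants; the same 60-movement session stream is then run through the
controller FSM in each mode. The REDUCED model needs fewer support vectors
(32 vs 47) and therefore less flash and less prediction time, while executing
the session just as accurately — the point of exploiting the reset-position
constraint. `footprint` is the exact serialized size of the packed model;
`cv` is 5-fold cross-validated per-sample accuracy; the session errors are
gesture-level, counting every wrong, missed or spurious movement once.

The same pipeline is scriptable from the shell:

```
emgctl generate --reps 10 --seed 1 --out session.csv
emgctl train --in session.csv --mode reduced --out model.emgsvm
emgctl run --stream session.csv --model model.emgsvm --out trace.csv
emgctl transfer --model model.emgsvm --corrupt 0.1 --seed 7
emgctl evaluate --subjects 20 --seed 1 --out report.json
```

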