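# Methods

This note documents the models behind `errpbandit`, the parameters that
matter, the reasoning behind the genuinely open design choices, and what
the synthetic data can and cannot show.

## Synthetic data

### Gestures

A gesture is a 4-vector: palm-normal (x, y, z) plus grab strength in
[0, 1]. Archetypes are `left = (−1, 0, 0, 0.1)`, `right = (+1, 0, 0, 0.1)`,
`forward (fist) = (0, 0, −1, 1.0)` — linearly separable directions with the
field's semantics (open tilted hand ≈ grab 0.1, fist = 1). A recorded
gesture is the mean of 10 subsamples (100 ms each), each perturbed by
isotropic Gaussian noise (default sd 0.3 per component, i.e. ≈0.1 after
averaging) with grab strength clipped to [0, 1] per subsample. The default
reflects that freely performed gestures vary visibly from trial to trial;
sensor dropouts and systematic per-user miscalibration are not modelled.

### EEG epochs

Epochs span −0.1 to 1.0 s around action onset, 64 channels, default
250 Hz (5 kHz generation is supported and exercises the same decimation
path at ~20× cost; 250 Hz keeps test suites fast without changing any
downstream count — both rates decimate to 50 Hz). Background noise is
i.i.d. unit-variance Gaussian per channel and sample. Erroneous trials add
`snr ×` a biphasic template — Gaussian-windowed positive peak at 0.30 s
(σ = 50 ms) minus a negative peak at 0.45 s (σ = 60 ms) — mixed through a
fixed fronto-central topography (smooth bump over the channel axis,
amplitude 1), with onset shifted per trial by a zero-mean Gaussian jitter
(sd 50 ms, truncated at ±150 ms) emulating the unknown subjective
error-recognition time.

`snr = 0.5` is a **calibration, not ground truth**: single-trial ErrP
amplitude relative to background EEG is not identifiable from published
summary statistics, so the default was chosen so that the full detection
pipeline lands in the ≈0.9 balanced-accuracy regime the closed loop is
designed around. The generator omits 1/f spectra (an optional component
exists but is off by default), ocular/muscular artifacts, electrode drift
and channel correlations; consequently, passing tests demonstrate that the
pipeline recovers a jittered low-frequency spatio-temporal pattern at
realistic operating points — not that it would reach the same numbers on
recorded EEG.

### Schedules

Training schedules place exactly `n_err` erroneous trials uniformly
without replacement (default 10 of 90, the 1:8 ratio). Test-phase error
content emerges from the closed loop instead of being scheduled.

## Detection pipeline

* **Preprocessing.** Per-channel mean removal; zero-phase 4th-order
  Butterworth band-pass 0.5–10 Hz applied at the native rate with maximal
  reflect padding; polyphase decimation to 50 Hz; then the feature window
  is cut. The band-pass runs before decimation and windowing because on
  ≤1.1 s segments the filter's edge transients otherwise dominate: applied
  to a 35-sample window the nominal stop band is simply not realised
  (measured ~11 dB instead of >20 dB rejection at 20 Hz). The realised
  band is identical.
* **xDAWN.** With non-overlapping, fixed-latency epochs the least-squares
  evoked estimate reduces to the Err-class average P; filters are the
  leading generalised eigenvectors of (P Pᵀ/T, Σ̂), Σ̂ the mean per-epoch
  data covariance ridge-regularised by 10⁻⁶ × mean channel variance
  (small synthetic sets can be rank-deficient). Fit once per dataset on
  the pooled windowed epochs of both windows; 8 components kept.
* **Features and classifier.** Row-major flattening (channel-major) of
  8 × 35 samples = 280 features per window. One linear SVM is trained on
  the pooled windowed epochs of both windows (the alternative — one
  classifier per window — is equally consistent with a single-classifier
  description; pooling doubles the scarce Err sample count and is adopted
  throughout). Features are z-scored with training-set statistics that are
  frozen and reapplied at test time — the classifier-transfer setting.
  Grid search maximises stratified 5-fold CV balanced accuracy over
  C ∈ {10⁰…10⁻⁶} × Err-class weight ∈ {1, 2, 4, 6, 8}; ties break toward
  larger C, then smaller weight (scan order with strict improvement), the
  decision threshold is fixed at 0, and the CV fold seed is logged.
* **Fusion.** r = 1 iff both windows decide NoErrP. For independent
  per-window decisions this gives a fused detection rate of
  1 − (1 − TPR)² and a fused pass rate of TNR².

## Bandit

Disjoint-arm LinUCB over a shared context: the action carries no features
of its own, so each arm keeps `(A_a, b_a)` over the 4-D gesture features,
initialised to `(I, 0)`. Selection maximises `θ̂_aᵀx + α√(xᵀA_a⁻¹x)` with
α = 2; ties break by fixed arm order (left < right < forward). The context
update `A_a += x xᵀ` applies on every trial; the payoff update `b_a += r x`
only has an effect for r = 1. No forgetting or discounting. Pre-training
replays one donor vector per gesture three times, always updating the
*designated* arm with r = 1 (the perfect-feedback reading): exactly 9
updates, all on the correct arms. Regret increments by 1 − r_t — it
follows the feedback channel, not the ground truth, so a missed error
(FN) leaves regret flat while a false alarm raises it.

### Context norm (a load-bearing choice)

Raw gesture vectors have unequal norms (‖fist‖ ≈ √2 vs ≈1) and, with
α = 2, a raw-context bandit explores almost blindly: a never-selected
arm's bonus α‖x‖ ≥ 2 exceeds any attainable payoff (≤1) for far longer
than a 90-trial session. Contexts are therefore unit-normalised and scaled
to a fixed norm c. Two constraints bound c:

* **Lower bound** — learning speed: the ~30 within-session updates an arm
  receives must outweigh the identity prior, i.e. 30 c² ≫ 1, so c ≳ 0.2.
* **Upper bound** — dilution robustness: an arm rewarded on only a
  fraction q of its selections (false positives withhold reward; realistic
  fused pass rates go down to q ≈ 0.7) must keep its UCB above the ≈ α c
  bonus of a never-selected arm, which asymptotically requires
  q > α c − (confidence credit), i.e. c ≲ q/α ≈ 0.35. At c = 0.5 this
  fails: sustained false positives drag the correct arm below unexplored
  alternatives and the false-positive rate, not the miss rate, dominates
  the error count — inverting the known behaviour of this reward scheme.

`c = 0.3` sits inside the band. With it, a pre-trained bandit under
perfect feedback and noiseless gestures commits zero errors in 90 trials,
while false negatives (which write payoff onto wrong arms) remain the
costlier fault, as they should be under reliable-positive fusion.

### Donor mismatch

The pre-training donor set represents gestures recorded from a *different*
person: raw palm-normal/grab features for the same nominal gesture differ
across people (hand size, orientation, which hand makes the fist). This is
modelled as a per-component N(0, 1.0) offset on the archetypes, drawn once
per donor. The magnitude is calibrated so closed-loop sessions under
realistic detection rates land at ≈90% action accuracy with errors
concentrated in the first half — the operating regime the method is built
for. With an exact-match donor (offset 0) the simulator is unrealistically
perfect (≈98–100%), early errors vanish, and the learning-dynamics
signatures (first-half > second-half errors; FN dominance) disappear with
them. The offset-0 configuration is retained as the idealised noiseless
condition.

## Feedback channels

`oracle` (r = 1 iff correct), `binary_noise` (per-window independent
Bernoulli decisions at the given TPR/TNR, fused as in the pipeline; a
`fused` flag interprets the rates as already-fused instead), and
`eeg_pipeline` (a synthetic epoch is generated per trial and classified by
a fitted detector). Degenerate probabilities consume no randomness, so a
(1, 1) noise channel replays an oracle session exactly under the same
seed. Test-phase gestures are drawn uniformly over the three types — the
neutral stand-in for a freely choosing human. Subject-skipped trials are
not modelled.

## Evaluation statistics

Balanced accuracy = (TPR + TNR)/2 with the erroneous trial as positive
class; action accuracy = 100 × (T − errors)/T with an optional
truncate-at-2-decimals mode for reproducing tabulated values that chop
repeating decimals (e.g. 19/90 → 78.88); Pearson correlation via scipy.
The Wilcoxon signed-rank test drops zero differences, assigns midranks to
ties, and enumerates the exact null (dynamic programming over all 2ⁿ sign
assignments, midranks doubled to integers) for n ≤ 25, falling back to the
normal approximation beyond; the package carries its own exact
implementation because the standard exact routine refuses ties and zeros.
Recomputed SEM/CI summaries are derived from the raw per-subject values
rather than copied, so discrepancies in published summary rows surface
instead of propagating.

## Problem sizes

Default experiment sizes are those of the study conditions: 4 training
sets × 90 trials (1:8 ratio), 90-trial test sessions, 64 channels.
Monte-Carlo tolerances in tests derive from binomial standard errors at
the stated sample sizes; session-battery statistics use 20–200 seeded
replicates, which bounds their standard errors well below the asserted
margins.

## Known limitations

* The EEG generator's noise model is white; real EEG is coloured and
  artifact-laden, and real ErrP morphology varies across subjects.
* Gesture archetypes and donor variability are plausible stand-ins; the
  true Leap feature distributions were never published.
* The bandit's zero-error guarantee is specific to three well-separated
  gestures and the calibrated context norm; more arms or overlapping
  gesture classes would reopen exploration errors.
* Relearning after a gesture-meaning switch is possible in principle
  (updates never stop) but is not exercised by the shipped experiments.
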