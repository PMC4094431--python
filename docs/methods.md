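# Methods

This note documents the models, parameters and design choices behind
`erdbci`, and what the synthetic-user experiments do and do not show.

## Signal model and features

EEG is represented at 256 Hz in microvolts. The front end emulates a
clinical amplifier: a causal 4th-order Butterworth band-pass 0.5–100 Hz and
a 2nd-order IIR notch at 50 Hz (Q = 30). Only causal filtering is used
anywhere — the system must run online — and every filter carries explicit
state, so processing a stream in blocks is numerically identical to
processing it at once (asserted to 1e-9 in the tests).

Features are logarithmic band powers from three bipolar derivations
(C3 = FC3−CP3, Cz = FCz−CPz, C4 = FC4−CP4) in the mu (9–13 Hz) and beta
(16–26 Hz) bands: band-pass (4th-order Butterworth), square, causal
rectangular moving average over 1.0 s (256 samples), natural log. The first
second of every fresh stream is warm-up while the average fills; it is
marked on the feature track and excluded from bias adaptation, and the
trial structure keeps it out of all classification windows. Column order is
fixed (C3-mu, Cz-mu, C4-mu, C3-beta, Cz-beta, C4-beta) but features are
always addressed by `(derivation, band)` identifiers, never by index. The
filter family and order are a design choice: any stable causal IIR meeting
the passband contract would do; Butterworth keeps the passband flat
(gain 1 ± 0.05 at 10 Hz, verified numerically).

## Artifact handling

Screening is two-stage, per trial epoch of band-filtered bipolar EEG:

1. **Statistics thresholding.** Amplitude: any |sample| > 100 µV. Kurtosis
   and probability (per-channel mean Gaussian log-likelihood under the
   pooled history fit): the trial statistic is z-scored against the same
   statistic of the last ≤ 20 trials and cut at the Student-t quantile
   (df = history−1) matching the normal z = 5 tail. The t-calibration
   matters: with only 4–10 reference trials a raw |z| > 5 cut on an
   estimated SD rejects ~2 % of clean trials, which measurably delays the
   first calibration; the calibrated cut holds the intended ~5σ
   false-rejection rate at every history size. Fewer than four history
   trials: amplitude only.
2. **Feature-outlier rejection** inside every calibration: a trial is
   dropped when any of its six trial-averaged features lies outside
   mean ± 3 SD of the remaining same-class trials (leave-one-out; zero
   spread never rejects). Requires ≥ 6 trials per class.

Clean-TPC counters that trigger calibration count trials that passed stage
1 at arrival; stage-2 rejections happen inside each calibration pass and do
not retroactively decrement the counters.

The online detector whitens each bipolar channel with the inverse transfer
function of a per-channel AR(11) model (least squares on the lagged design,
pooled over clean epochs without straddling epoch boundaries; stability of
the characteristic roots is enforced). The flag threshold is the 99th
percentile of absolute training residuals, fixing the raw exceedance rate
at 1 % by construction; display events hold for 0.5 s past offset. A
consequence worth knowing: at a 1 % raw rate the *displayed* flag is on a
large fraction of the time — the percentile is configurable where a quieter
display is wanted.

## Auto-calibration

Calibration always runs on all collected artifact-free trials:
feature-outlier rejection → Fisher-criterion selection
`(μ₁−μ₂)²/(σ₁²+σ₂²)` (sample variances) of one of the six features, using
trial-averaged values over the classification period [3, 7) s (averaging is
a variance-reduction choice; the period is fixed by the trial structure) →
LooCV training-window selection → LDA → output normalization → AR refit.

Window selection splits [3, 7) into eight 0.5 s windows. For each window,
leave-one-out: train LDA on the window-averaged feature of the other
trials, apply it sample-wise across the full held-out period, average over
folds into a 4 s accuracy curve; the window with the highest median curve
wins, ties to the earliest. A constant feature falls back to window 0 with
a warning. Note a structural property: the median of the 4 s curve can only
see separability that is *sustained* over a substantial part of the period;
an effect confined to a single 0.5 s window leaves all medians at chance.
Physiological ERD is sustained, so this is the intended regime.

The LDA on the scalar selected feature uses the maximum-likelihood pooled
variance (floored at 1e-12), making the model an exact function of the
class sufficient statistics (duplicating every trial changes nothing). The
output is affinely normalized so the training-class means map to −1
(non-control) and +1 (imagery); the online label is imagery for output > 0.
Initial calibration needs 9 clean TPC for all three classes and runs the
whole pipeline for left-vs-non-control and right-vs-non-control, keeping
the hand with the higher median LooCV accuracy (ties: higher Fisher score,
then right). Re-calibration needs 5 new clean TPC for the two active
classes; the new model replaces the old atomically at the next trial, and
counters reset.

Bias adaptation for self-paced use shifts the output so its 90th percentile
over a ≥ 30 s non-control run (warm-up excluded) is zero, capping the
non-control above-zero rate at 10 % without touching the weights. The rule
is idempotent on the same run.

## Paradigms

**Co-adaptive (cue-guided).** 4 runs × 36 trials; trial: fixation 0–2 s,
cue at 2 s, imagery until 7 s, pause uniform 2–3 s. Cue order uses permuted
balanced blocks (3 classes before calibration, 2 after, switching at the
next trial) — this guarantees per-run class balance and first calibration
within five minutes, which i.i.d. cue draws cannot. Feedback (online phase
only) is positive-only: a bar proportional to |output| (clipped at 1) shown
between 3.75 and 7 s only while the predicted label matches the cue; a
smiley reward fires when prediction and cue match for > 2 s cumulatively in
[3, 7). Artifact-flag, cue, calibration, class-selection, feedback (logged
at 4 Hz) and reward events form the session log; a session replays
bit-identically from (config, seed).

**Self-paced (rotating arrow).** Six segments, 4 s of arrow travel per
segment; targets are scheduled uniformly 2–5 segments clockwise after the
previous target. Run 1 (60 s, non-control) only adapts the bias; runs 2–3
(420 s) are scored. An activation fires per uninterrupted full second above
the 0.5 threshold (dwell clock resets at segment boundaries), so a 4 s
super-threshold span scores the maximum four points. Target segments show
real feedback (red above threshold); non-target segments show sham feedback
— Gaussian length (0.25 ± 0.08, clipped below 0.45) that can never reach
the activation display — while real false-positive activations are still
logged for evaluation. A scored target freezes the arrow for 3 s
(refractory, excluded from scoring; the final refractory may spill past the
nominal run end). Segment outcomes: target → TP per activation, FN if
none; non-target → FP per activation, TN if none.

## Evaluation statistics

Cue-paced sessions are scored by the sample-wise accuracy over all
online-phase feedback trials (per-run curves are available too) and its
peak. Significance uses the one-sided adjusted-Wald bound around chance
(z = 2.3263 at p = 0.01) at N = 2 × TPC — 61.0 % at 54 TPC. The Youden
index optimizes J = TPR − FPR over thresholds × dwell times (0.5–4 s, step
0.5 s), counting a trial as activated when its output holds above threshold
for the dwell; it is reported in-sample, with the optimism that implies.

The peak is a maximum over ~1000 strongly correlated time points and
therefore exceeds the single-point bound far more often than α under the
null. `permutation_peak_threshold` provides the statistically matched
band: it permutes trial labels of the recorded predictions (preserving the
curve's correlation structure) and returns the 99th percentile of null
peaks — typically ~66–70 % where the single-point bound is 61 %. Null-user
claims in the tests use this band; strong-user claims use the conventional
61.0 % bound.

Self-paced sessions are scored by balanced accuracy (mean of TPR and TNR,
in percent), which pins the chance level at 50 % regardless of the ~30 %
target prevalence; its chance band conservatively uses the number of
target segments as N.

## Synthetic users

Each of the six electrodes carries pink noise (Paul Kellet's 1/f IIR
approximation, 5 µV RMS) plus a 1 µV RMS white floor — the floor keeps AR
fitting well-posed. Sensorimotor rhythms are amplitude-modulated narrowband
Gaussian noise (band-pass-filtered white noise; 6 µV RMS mu, 5 µV RMS
beta), injected anti-phase (±half) into the anterior/posterior electrode of
each pair so the bipolar derivation carries them at full amplitude.
Narrowband noise rather than pure sines gives realistic spectra while
keeping band power exactly controllable. During imagery the envelope of
the targeted (derivation, band) rhythms is multiplied by √(1−depth) after a
0.5 s reaction latency; mapping is contralateral (right hand → C3, left
hand → C4). With these amplitudes the background contributes ~10 % of
in-band power, so a planted depth of 0.5 appears in the log feature as
≈ log 0.5 (verified to ±0.15). Every noise source has its own child RNG
stream, so generated EEG is independent of how a session chops the stream
into blocks. Artifacts are Poisson-timed Hann-windowed 400 µV transients,
0.2–0.5 s, on one random electrode, with ground-truth event lists.

Presets: `strong` (depth 0.5, C3-mu, right hand), `weak` (0.2), `null` (no
ERD), `artifacty` (strong + 6 transients/min).

**What the simulations show and don't.** They validate the machinery:
end-to-end recovery of the planted class and feature, calibration timing,
chance-level calibration of the statistics, and the mechanics of both
paradigms. They do not model non-stationarity, user learning, eye/EMG
spectral structure, volume conduction, or electrode artifacts beyond
broadband transients — so passing tests demonstrate correct system
behavior under the stated signal model, not expected human performance.
One informative coincidence of the model: per-sample log band-power noise
is governed by the band's noise bandwidth times the 1 s average
(sd ≈ 0.5), so a depth-0.5 user has per-sample discriminability d' ≈ 1.2.
In the closed loop that yields peak accuracies near 80 % and self-paced
balanced accuracies around 64 % that clear the conservative chance band
only about half the time — the same qualitative picture the fixed 0.5
activation threshold produced with human users.

## Numerical choices and problem sizes

Ties: window selection → earliest; class selection → Fisher, then right;
Youden grid → first cell in (threshold, dwell) order. Variance floors of
1e-12 guard degenerate features; log power is floored at 1e-20 µV². EDF is
written as 16-bit with 1 s records, symmetric physical range encoded
exactly as scaled. Simulation-based tests use 10 seeded sessions (full
24-minute co-adaptive + 15-minute self-paced) per condition and 20 seeds
for calibration-level recovery; Monte-Carlo checks use 10⁴ binomial draws
and 500 label permutations. These sizes give sub-percent standard errors
on the reported means while keeping a full verification run in the
minutes range on one core.
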