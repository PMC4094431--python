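"""Two-stage trial screening and online AR-residual artifact detection.

Simulates an artifact-prone user (frequent 400 uV transients), screens
trials by amplitude/kurtosis/probability statistics, fits the AR(11) model
on the clean ones and shows the real-time detector flagging a fresh
transient within milliseconds.
"""

import numpy as np

import erdbci as e

FS = 256
params = e.preset("artifacty")
user = e.SimUser(params, seed=2)
pipeline = e.FeaturePipeline()

history, clean_epochs, n_flagged = [], [], 0
for k in range(30):
    seg = user.generate_constant("non-control", 7 * FS)
    seg, truth = e.inject_artifacts(seg, params, user.rng)
    bipolar, _ = pipeline.process(seg)
    epoch = e.EEGSegment(bipolar.data, FS, list(bipolar.channel_labels))
    verdict = e.screen_trial_stats(epoch, history[-20:])
    history.append(epoch)
    if verdict.clean:
        clean_epochs.append(epoch)
    else:
        n_flagged += 1
print(f"screened 30 trials: {n_flagged} flagged, {len(clean_epochs)} clean")

ar = e.fit_ar(clean_epochs)
print(f"AR(11) fitted; residual thresholds (uV): {np.round(ar.residual_threshold, 2)}")

fresh = user.generate_constant("non-control", 10 * FS)
fresh.data[5 * FS :, 0] += 300.0  # a 300 uV shift at t = 5 s
bipolar = e.bipolar_derive(e.preprocess(fresh))
raw = e.detect_artifact_online(bipolar, ar, hold=0.0)
base_rate = raw[2 * FS : 5 * FS].mean()
onset = np.flatnonzero(raw[5 * FS :])[0] / FS
print(f"baseline residual exceedance rate: {100 * base_rate:.1f} % of samples "
      "(~1 % by construction of the 99th-percentile threshold)")
print(f"transient injected at 5.000 s -> first detection {1000 * onset:.0f} ms later")
print("(the on-screen yellow dot additionally stays on 0.5 s past each offset)")
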