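"""Self-paced brain-switch training with the co-adaptively trained model.

Runs the rotating-arrow paradigm: a 60 s non-control run adapts the
classifier bias, then two 7-minute runs are scored — an activation per full
second of super-threshold output, sham feedback in non-target segments, a
3 s refractory pause after scored targets. Prints the imbalance-corrected
(balanced) accuracy against its conservative chance band.
"""

import erdbci as e

user = e.SimUser(e.preset("strong"), seed=1)
coad = e.run_coadaptive_session(user, seed=1)
result = e.run_selfpaced_session(user, coad.model, seed=1)

c = result.counts
print(f"segments: {len(result.records)}  (targets: {result.n_target_segments}, "
      f"{100 * c.target_fraction:.1f} %)")
print(f"TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}; "
      f"points scored: {sum(r.points for r in result.records)}")
print(f"balanced accuracy: {result.balanced_accuracy_percent:.1f} %")
print(f"chance threshold (p = 0.01, {result.n_target_segments} targets): "
      f"{result.chance_threshold_percent:.1f} % -> "
      f"{'significant' if result.significant else 'not significant'}")
print(f"bias shift applied in run 1: {result.model.out_shift - coad.model.out_shift:+.2f} "
      "(output units)")
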