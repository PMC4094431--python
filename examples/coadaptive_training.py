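"""A complete closed-loop co-adaptive training session.

The system starts cue-ing three classes (non-control, left, right),
auto-calibrates at nine artifact-free trials per class, picks the hand with
the better leave-one-out accuracy, then gives positive-only feedback and
re-calibrates every five new clean trials per class — 4 runs x 36 trials,
24 minutes of simulated session time.
"""

import erdbci as e

user = e.SimUser(e.preset("strong"), seed=1)
result = e.run_coadaptive_session(user, seed=1)

model = result.model
print(f"first calibration at {result.first_calibration_time():.1f} s "
      f"({result.first_calibration_time() / 60:.1f} min)")
print(f"selected class: {model.selected_class}; feature: {model.feature_id}; "
      f"training window {model.train_window} ([{3 + 0.5 * model.train_window:.1f}, "
      f"{3.5 + 0.5 * model.train_window:.1f}) s)")
print(f"re-calibrations over the session: {model.calib_count}")
curve = result.accuracy_curve()
print(f"peak sample-wise accuracy over {len(result.online_records)} feedback "
      f"trials: {curve.peak_percent:.1f} %")
print(f"chance threshold (54 TPC, p = 0.01): {e.chance_threshold(54):.1f} % -> "
      f"{'significant' if curve.peak_percent > e.chance_threshold(54) else 'not significant'}")
rewards = sum(r.rewarded for r in result.online_records)
print(f"reward smileys earned: {rewards}/{len(result.online_records)} trials")
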