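"""Chance-level statistics for small-sample BCI accuracy claims.

An observed accuracy only means control if it clears the confidence band
around the theoretical 50 % chance level. Prints the one-sided adjusted-Wald
bounds (p = 0.01) for cue-paced trial counts and for self-paced target
segments, and the permutation-calibrated band for the optimistic *peak*
statistic.
"""

import numpy as np

import erdbci as e
from erdbci.evaluation import permutation_peak_threshold

print("cue-paced, per-timepoint accuracy (N = 2 x TPC):")
for tpc in (9, 20, 54, 200):
    print(f"  {tpc:4d} trials/class -> significant above {e.chance_threshold(tpc):.1f} %")

print("self-paced balanced accuracy (conservative N = target segments):")
for n in (10, 30, 59, 200):
    print(f"  {n:4d} target segments -> significant above {e.selfpaced_chance_threshold(n):.1f} %")

rng = np.random.default_rng(0)
preds = rng.choice(["mi", "nc"], size=(108, 1024))
labels = np.array(["mi", "nc"] * 54)
band = permutation_peak_threshold(preds, labels, rng=rng)
print("the PEAK of a sample-wise accuracy curve is a maximum over correlated")
print(f"time points; its own chance band at 54 TPC is {band:.1f} %, above the "
      f"{e.chance_threshold(54):.1f} % single-point bound")
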