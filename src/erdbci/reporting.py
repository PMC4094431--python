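"""Metrics JSON assembly from trial and segment records."""

from __future__ import annotations

import numpy as np

from .classifier import CLASSIFY_START
from .coadaptive import TrialRecord
from .evaluation import (
    balanced_accuracy,
    chance_threshold,
    samplewise_accuracy,
    selfpaced_chance_threshold,
    youden_index,
)
from .selfpaced import SegmentRecord


def coadaptive_metrics(
    records: list[TrialRecord], selected_class: str, fs: float = 256.0
) -> dict:
    """Peak sample-wise accuracy, Youden optimum and chance band for one
    co-adaptive session's online feedback trials."""
    online = [r for r in records if r.online and r.predictions is not None]
    if not online:
        return {"status": "no online trials"}
    preds = np.stack([r.predictions for r in online])
    labels = np.array([r.label for r in online])
    t = CLASSIFY_START + np.arange(preds.shape[1]) / fs
    curve = samplewise_accuracy(preds, labels, t)
    outputs = [r.outputs for r in online]
    j, theta, dwell, _ = youden_index(outputs, labels, selected_class, fs=fs)
    tpc = int(min(np.sum(labels == selected_class), np.sum(labels != selected_class)))
    thr = chance_threshold(tpc) if tpc >= 2 else float("nan")
    return {
        "peak_accuracy_percent": round(curve.peak_percent, 2),
        "youden_index": round(j, 4),
        "youden_threshold": theta,
        "youden_dwell_seconds": dwell,
        "n_online_trials": len(online),
        "trials_per_class": tpc,
        "chance_threshold_percent": round(thr, 2),
        "significant": bool(curve.peak_percent > thr),
        "selected_class": selected_class,
    }


def selfpaced_metrics(records: list[SegmentRecord]) -> dict:
    """Balanced accuracy and its conservative chance band for one self-paced
    session's segment records."""
    if not records:
        return {"status": "no segments"}
    tp = sum(r.tp for r in records)
    fp = sum(r.fp for r in records)
    tn = sum(r.tn for r in records)
    fn = sum(r.fn for r in records)
    n_target = sum(r.is_target for r in records)
    from .evaluation import ConfusionCounts

    counts = ConfusionCounts(tp, fp, tn, fn, target_fraction=n_target / len(records))
    bal = balanced_accuracy(counts)
    thr = selfpaced_chance_threshold(n_target) if n_target >= 2 else float("nan")
    return {
        "balanced_accuracy_percent": round(bal, 2),
        "chance_threshold_percent": round(thr, 2),
        "significant": bool(bal > thr),
        "n_segments": len(records),
        "n_target_segments": n_target,
        "target_fraction": round(counts.target_fraction, 4),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "total_points": sum(r.points for r in records),
    }
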