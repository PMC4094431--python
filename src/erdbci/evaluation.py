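"""Session statistics: peak sample-wise accuracy, Youden index, chance bands.

The cue-guided paradigm is scored by the accuracy at every sample point of
the classification period [3, 7) s and its peak. For comparability with
asynchronous operation, a Youden index (TPR - FPR) is optimized over a
threshold x dwell-time grid (dwell 0.5-4 s in 0.5 s steps). Significance
against chance uses one-sided adjusted-Wald confidence bounds around the
theoretical chance level of 0.5; the self-paced variant conservatively uses
the number of target segments (the smaller class) as the sample size.
Self-paced confusion matrices are row-normalized (balanced accuracy), which
pins the theoretical chance level to 50 % regardless of target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class AccuracyCurve:
    """Sample-wise accuracy over the classification period."""

    t: np.ndarray  # seconds within the trial
    acc: np.ndarray  # fraction correct per sample point

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.t.shape != self.acc.shape:
            raise ValueError("t and acc must align")

    @property
    def peak(self) -> float:
        return float(self.acc.max())

    @property
    def peak_percent(self) -> float:
        return 100.0 * self.peak


@dataclass
class ConfusionCounts:
    """Event counts for self-paced scoring."""

    tp: int
    fp: int
    tn: int
    fn: int
    target_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def samplewise_accuracy(
    predictions: np.ndarray, true_labels: np.ndarray, t: np.ndarray | None = None
) -> AccuracyCurve:
    """Fraction of trials predicted correctly at every sample point.

    ``predictions``: (n_trials, n_samples) predicted labels;
    ``true_labels``: (n_trials,). All trials must share one time base.
    """
    predictions = np.asarray(predictions)
    true_labels = np.asarray(true_labels)
    if predictions.ndim != 2:
        raise ValueError("predictions must be (n_trials, n_samples)")
    if predictions.shape[0] != true_labels.shape[0]:
        raise ValueError("one true label per trial required")
    if np.unique(true_labels).size < 2:
        raise ValueError("need at least one trial per class")
    acc = (predictions == true_labels[:, None]).mean(axis=0)
    if t is None:
        t = 3.0 + np.arange(predictions.shape[1]) / 256.0
    return AccuracyCurve(np.asarray(t), acc)


def _spans_above(x: np.ndarray, threshold: float) -> list[int]:
    """Lengths (in samples) of maximal runs with x > threshold."""
    above = x > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(x))
    return [b - a for a, b in zip(starts, stops)]


DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
DEFAULT_DWELLS = tuple(np.round(np.arange(0.5, 4.01, 0.5), 10))


def youden_index(
    outputs: list[np.ndarray],
    labels: np.ndarray,
    positive_label,
    fs: float = 256.0,
    thresholds=DEFAULT_THRESHOLDS,
    dwells=DEFAULT_DWELLS,
) -> tuple[float, float, float, np.ndarray]:
    """Best J = TPR - FPR over a threshold x dwell grid.

    A trial activates at grid cell (theta, d) when its output exceeds theta
    continuously for at least d seconds. MI trials: activation -> TP else
    FN; non-control trials: activation -> FP else TN. Returns
    (J*, theta*, d*, J_grid); ties resolve to the first cell in
    (threshold, dwell) row-major order.
    """
    if len(thresholds) == 0 or len(dwells) == 0:
        raise ValueError("empty grid")
    labels = np.asarray(labels)
    if len(outputs) != len(labels):
        raise ValueError("one output track per trial required")
    is_pos = labels == positive_label
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    grid = np.zeros((len(thresholds), len(dwells)))
    # longest super-threshold span per (trial, threshold): dwell check is a comparison
    for i_t, theta in enumerate(thresholds):
        longest = np.array(
            [max(_spans_above(np.asarray(o, float), theta), default=0) for o in outputs]
        )
        for i_d, d in enumerate(dwells):
            active = longest >= int(round(d * fs))
            tpr = np.sum(active & is_pos) / n_pos
            fpr = np.sum(active & ~is_pos) / n_neg
            grid[i_t, i_d] = tpr - fpr
    flat = int(np.argmax(grid))
    i_t, i_d = np.unravel_index(flat, grid.shape)
    return float(grid[i_t, i_d]), float(thresholds[i_t]), float(dwells[i_d]), grid


def _adjusted_wald_upper(n: int, alpha: float) -> float:
    """One-sided adjusted-Wald upper bound on chance (p = 0.5) accuracy."""
    z = sps.norm.ppf(1.0 - alpha)
    n_adj = n + z**2
    p_adj = (n / 2.0 + z**2 / 2.0) / n_adj
    return p_adj + z * np.sqrt(p_adj * (1.0 - p_adj) / n_adj)


def chance_threshold(n_trials_per_class: int, alpha: float = 0.01) -> float:
    """Significance threshold (percent) for two-class cue-paced accuracy.

    Upper adjusted-Wald bound of the chance binomial at N = 2 * TPC trials.
    With 54 TPC and alpha = 0.01 this is the familiar 61.0 %.
    """
    if n_trials_per_class < 2:
        raise ValueError("need at least 2 trials per class")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    return 100.0 * _adjusted_wald_upper(2 * n_trials_per_class, alpha)


def selfpaced_chance_threshold(n_target_segments: int, alpha: float = 0.01) -> float:
    """Balanced-accuracy chance threshold (percent) for self-paced scoring.

    Conservative: the adjusted-Wald bound is evaluated at the number of
    target segments, the smaller of the two segment classes.
    """
    if n_target_segments < 2:
        raise ValueError("need at least 2 target segments")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    return 100.0 * _adjusted_wald_upper(n_target_segments, alpha)


def permutation_peak_threshold(
    predictions: np.ndarray,
    true_labels: np.ndarray,
    alpha: float = 0.01,
    n_permutations: int = 500,
    rng: np.random.Generator | None = None,
) -> float:
    """Chance band for the *peak* of a sample-wise accuracy curve, in percent.

    The peak statistic is optimistic: it is the maximum over many correlated
    time points, so its null distribution sits above the single-point
    binomial bound. This Monte-Carlo null permutes the trial labels of the
    recorded predictions (preserving the temporal correlation of the curve)
    and returns the (1 - alpha) quantile of the null peaks.
    """
    predictions = np.asarray(predictions)
    true_labels = np.asarray(true_labels)
    classes = np.unique(true_labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if rng is None:
        rng = np.random.default_rng(0)
    hits = predictions == classes[0]  # (n_trials, n_t); other class = ~hits
    n = len(true_labels)
    peaks = np.empty(n_permutations)
    labels = true_labels.copy()
    for i in range(n_permutations):
        rng.shuffle(labels)
        is_a = labels == classes[0]
        acc = (hits[is_a].sum(axis=0) + (~hits[~is_a]).sum(axis=0)) / n
        peaks[i] = acc.max()
    return 100.0 * float(np.quantile(peaks, 1.0 - alpha))


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Mean of TPR and TNR in percent (class-imbalance-corrected accuracy)."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no target events")
    if counts.tn + counts.fp == 0:
        raise ValueError("no non-target events")
    tpr = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    return 100.0 * (tpr + tnr) / 2.0
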