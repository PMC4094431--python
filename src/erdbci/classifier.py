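"""Auto-calibrating LDA on one auto-selected log band-power feature.

Calibration runs whenever enough artifact-free trials per class (TPC) are
available — nine initially, five new ones for every re-calibration — and
always works on all collected artifact-free trials:

1. leave-one-out feature-outlier rejection per class,
2. Fisher-criterion selection of the single most discriminative of the six
   (derivation, band) features over the classification period [3, 7) s,
3. selection of the best of eight adjacent 0.5 s training windows by
   leave-one-out cross-validation (LooCV), judged by the median of the
   sample-wise 4 s accuracy curve,
4. LDA training on the window-averaged feature plus an affine output
   normalization that maps the two class means to -1 (non-control) and +1
   (movement imagery),
5. an AR(11) refit for the online artifact detector.

At initial calibration the whole pipeline is run for left-vs-non-control and
right-vs-non-control and the hand with the higher median LooCV accuracy is
kept for the rest of the session.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .artifacts import ARModel, fit_ar, reject_feature_outliers
from .signals import FeatureTrack

NON_CONTROL = "non-control"
LEFT = "left"
RIGHT = "right"

CLASSIFY_START = 3.0  # s within trial
CLASSIFY_STOP = 7.0
N_WINDOWS = 8
WINDOW_SECONDS = 0.5
INITIAL_TPC = 9
RECALIB_TPC = 5
VAR_FLOOR = 1e-12


def fisher_score(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Fisher criterion (mean_a - mean_b)^2 / (var_a + var_b).

    Sample variances (ddof=1). Zero spread in both groups yields 0 for equal
    means and +inf otherwise (a perfectly separating degenerate feature).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size < 2 or x_b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if not (np.all(np.isfinite(x_a)) and np.all(np.isfinite(x_b))):
        raise ValueError("non-finite samples")
    num = (x_a.mean() - x_b.mean()) ** 2
    den = x_a.var(ddof=1) + x_b.var(ddof=1)
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / den)


def train_lda(x: np.ndarray, labels: np.ndarray, positive_label) -> tuple[float, float]:
    """Fisher LDA on a scalar feature.

    Returns (weight, bias) of the discriminant ``w * x + b`` whose sign is
    positive toward ``positive_label``. Uses the maximum-likelihood pooled
    within-class variance (floored at 1e-12) — a function of the class
    sufficient statistics only, so duplicating every trial leaves the model
    unchanged. Closed form: w = (mu_pos - mu_neg) / s2 with the boundary at
    the midpoint of the class means.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    pos = x[labels == positive_label]
    neg = x[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {uniq.size}")
    mu_p, mu_n = pos.mean(), neg.mean()
    s2 = (pos.size * pos.var() + neg.size * neg.var()) / (pos.size + neg.size)
    s2 = max(s2, VAR_FLOOR)
    w = (mu_p - mu_n) / s2
    b = -w * (mu_p + mu_n) / 2.0
    return float(w), float(b)


def loocv_window_select(
    tracks: list[np.ndarray],
    labels: np.ndarray,
    fs: float = 256.0,
    n_windows: int = N_WINDOWS,
    positive_label=None,
) -> tuple[int, np.ndarray]:
    """Pick the best 0.5 s LDA training window by leave-one-out CV.

    ``tracks``: per trial, the selected feature sampled over the
    classification period [3, 7) s (typically 1024 samples at 256 Hz).
    For every window the classifier trained on window-averaged values of the
    other trials is applied sample-wise to the whole held-out trial; fold
    averaging yields one 4 s accuracy curve per window. The window with the
    highest median accuracy wins; ties go to the earliest window.

    Returns (window_index, accuracy_curves) with curves shaped
    ``(n_windows, n_samples)``.
    """
    labels = np.asarray(labels)
    n_trials = len(tracks)
    if n_trials != len(labels):
        raise ValueError("one label per trial required")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    for cls in classes:
        if np.sum(labels == cls) < 5:
            raise ValueError("need >= 5 trials per class for LooCV")
    if positive_label is None:
        positive_label = classes[-1]
    tracks_arr = np.asarray(tracks, dtype=float)  # (n_trials, n_samples)
    n_samples = tracks_arr.shape[1]
    win_len = int(round(WINDOW_SECONDS * fs))
    if n_windows * win_len > n_samples:
        raise ValueError("classification period shorter than the window grid")

    if np.ptp(tracks_arr) < 1e-12:
        warnings.warn("degenerate constant feature; falling back to window 0")
        return 0, np.full((n_windows, n_samples), 0.5)

    # window-averaged feature per (trial, window)
    win_means = np.stack(
        [tracks_arr[:, w * win_len : (w + 1) * win_len].mean(axis=1) for w in range(n_windows)],
        axis=1,
    )
    is_pos = labels == positive_label
    curves = np.zeros((n_windows, n_samples))
    for w in range(n_windows):
        correct = np.zeros((n_trials, n_samples), dtype=bool)
        for i in range(n_trials):
            mask = np.ones(n_trials, dtype=bool)
            mask[i] = False
            weight, bias = train_lda(win_means[mask, w], labels[mask], positive_label)
            out = weight * tracks_arr[i] + bias
            correct[i] = (out > 0) == is_pos[i]
        curves[w] = correct.mean(axis=0)
    medians = np.median(curves, axis=1)
    best = int(np.argmax(medians))  # argmax returns the earliest maximum
    return best, curves


@dataclass
class ClassifierModel:
    """A calibrated single-feature LDA with output normalization.

    The normalized output ``out_scale * (w x + b) + out_shift`` maps the
    non-control training mean to -1 and the movement-imagery training mean
    to +1; the online label is MI for output > 0.
    """

    feature_id: tuple[str, str]
    train_window: int
    weight: float
    bias: float
    out_scale: float
    out_shift: float
    selected_class: str
    calib_count: int = 1
    ar: ARModel | None = None
    loocv_median_accuracy: float = float("nan")
    fisher: float = float("nan")

    def __post_init__(self) -> None:
        self.feature_id = tuple(self.feature_id)  # type: ignore[assignment]
        if not 0 <= self.train_window < N_WINDOWS:
            raise ValueError("train_window out of range")

    def apply(self, feat) -> tuple[np.ndarray, np.ndarray]:
        """Normalized output and predicted label per sample.

        ``feat`` may be a :class:`FeatureTrack` (the model's feature column is
        taken) or an array of the selected feature's values.
        """
        if isinstance(feat, FeatureTrack):
            x = feat.column(self.feature_id)
        else:
            x = np.asarray(feat, dtype=float)
        out = self.out_scale * (self.weight * x + self.bias) + self.out_shift
        labels = np.where(out > 0, self.selected_class, NON_CONTROL)
        return out, labels

    def to_json(self) -> str:
        d = {
            "feature_id": list(self.feature_id),
            "train_window": self.train_window,
            "weight": self.weight,
            "bias": self.bias,
            "out_scale": self.out_scale,
            "out_shift": self.out_shift,
            "selected_class": self.selected_class,
            "calib_count": self.calib_count,
            "loocv_median_accuracy": self.loocv_median_accuracy,
            "fisher": self.fisher,
        }
        if self.ar is not None:
            d["ar"] = {
                "coeffs": self.ar.coeffs.tolist(),
                "residual_threshold": self.ar.residual_threshold.tolist(),
                "fs": self.ar.fs,
                "order": self.ar.order,
            }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        ar = d.pop("ar", None)
        model = cls(
            feature_id=tuple(d["feature_id"]),
            train_window=d["train_window"],
            weight=d["weight"],
            bias=d["bias"],
            out_scale=d["out_scale"],
            out_shift=d["out_shift"],
            selected_class=d["selected_class"],
            calib_count=d.get("calib_count", 1),
            loocv_median_accuracy=d.get("loocv_median_accuracy", float("nan")),
            fisher=d.get("fisher", float("nan")),
        )
        if ar is not None:
            model.ar = ARModel(
                np.array(ar["coeffs"]),
                np.array(ar["residual_threshold"]),
                fs=ar["fs"],
                order=ar["order"],
            )
        return model


@dataclass
class Trial:
    """One cue-aligned, screening-clean trial ready for calibration."""

    label: str
    feature_track: np.ndarray  # (n_samples, 6) over [3, 7) s
    feature_means: np.ndarray  # (6,) trial-averaged over [3, 7) s
    eeg: object | None = None  # bipolar EEGSegment epoch, for the AR refit


@dataclass
class TrialStore:
    """Clean labeled trials plus new-TPC counters since the last calibration."""

    feature_ids: list[tuple[str, str]]
    trials: dict[str, list[Trial]] = field(default_factory=dict)
    new_since_calibration: dict[str, int] = field(default_factory=dict)

    def add(self, trial: Trial) -> None:
        self.trials.setdefault(trial.label, []).append(trial)
        self.new_since_calibration[trial.label] = (
            self.new_since_calibration.get(trial.label, 0) + 1
        )

    def count(self, label: str) -> int:
        return len(self.trials.get(label, []))

    def new_count(self, label: str) -> int:
        return self.new_since_calibration.get(label, 0)

    def reset_new_counts(self, labels) -> None:
        for lbl in labels:
            self.new_since_calibration[lbl] = 0

    def ready_initial(self, labels=(NON_CONTROL, LEFT, RIGHT), tpc: int = INITIAL_TPC) -> bool:
        return all(self.count(lbl) >= tpc for lbl in labels)

    def ready_recalibration(self, labels, tpc: int = RECALIB_TPC) -> bool:
        return all(self.new_count(lbl) >= tpc for lbl in labels)


def _calibrate_pair(
    store: TrialStore, mi_label: str, fs: float, fit_ar_model: bool = True
) -> ClassifierModel:
    """Full calibration pipeline for one MI class against non-control."""
    trials = store.trials.get(mi_label, []) + store.trials.get(NON_CONTROL, [])
    labels = np.array([t.label for t in trials])
    feats = np.stack([t.feature_means for t in trials])

    kept, _ = reject_feature_outliers(feats, labels)
    trials = [trials[i] for i in kept]
    labels = labels[kept]
    feats = feats[kept]

    is_mi = labels == mi_label
    scores = np.array(
        [fisher_score(feats[is_mi, j], feats[~is_mi, j]) for j in range(feats.shape[1])]
    )
    j_best = int(np.argmax(scores))
    feature_id = store.feature_ids[j_best]

    tracks = [t.feature_track[:, j_best] for t in trials]
    window, curves = loocv_window_select(tracks, labels, fs=fs, positive_label=mi_label)

    win_len = int(round(WINDOW_SECONDS * fs))
    win_means = np.array(
        [tr[window * win_len : (window + 1) * win_len].mean() for tr in tracks]
    )
    weight, bias = train_lda(win_means, labels, mi_label)

    raw_mi = weight * win_means[is_mi].mean() + bias
    raw_nc = weight * win_means[~is_mi].mean() + bias
    span = raw_mi - raw_nc
    if abs(span) < VAR_FLOOR:
        out_scale, out_shift = 1.0, 0.0
    else:
        out_scale = 2.0 / span
        out_shift = -(raw_mi + raw_nc) / span

    ar = None
    if fit_ar_model:
        epochs = [t.eeg for t in trials if t.eeg is not None]
        if epochs:
            ar = fit_ar(epochs)

    return ClassifierModel(
        feature_id=feature_id,
        train_window=window,
        weight=weight,
        bias=bias,
        out_scale=out_scale,
        out_shift=out_shift,
        selected_class=mi_label,
        ar=ar,
        loocv_median_accuracy=float(np.median(curves[window])),
        fisher=float(scores[j_best]),
    )


def select_control_class(store: TrialStore, fs: float = 256.0) -> str:
    """Choose the MI hand with the higher median LooCV accuracy vs non-control.

    Ties fall back to the higher Fisher score of the selected feature, then
    to the right hand.
    """
    left = _calibrate_pair(store, LEFT, fs, fit_ar_model=False)
    right = _calibrate_pair(store, RIGHT, fs, fit_ar_model=False)
    if left.loocv_median_accuracy > right.loocv_median_accuracy:
        return LEFT
    if right.loocv_median_accuracy > left.loocv_median_accuracy:
        return RIGHT
    if left.fisher > right.fisher:
        return LEFT
    return RIGHT


def calibrate(
    store: TrialStore,
    mi_label: str | None = None,
    previous: ClassifierModel | None = None,
    fs: float = 256.0,
) -> ClassifierModel | None:
    """(Re-)calibrate when enough clean TPC are available; else return None.

    Initial calibration (``previous is None``) requires nine clean TPC for
    all three classes and runs class selection unless ``mi_label`` is given.
    Re-calibration requires five new clean TPC for the two active classes
    and trains on all collected clean trials; counters reset afterwards.
    """
    if previous is None:
        if not store.ready_initial():
            return None
        if mi_label is None:
            mi_label = select_control_class(store, fs=fs)
        model = _calibrate_pair(store, mi_label, fs)
        model.calib_count = 1
        store.reset_new_counts([NON_CONTROL, LEFT, RIGHT])
        return model
    active = [NON_CONTROL, previous.selected_class]
    if not store.ready_recalibration(active):
        return None
    model = _calibrate_pair(store, previous.selected_class, fs)
    model.calib_count = previous.calib_count + 1
    store.reset_new_counts(active)
    return model


def adapt_bias(
    model: ClassifierModel, nc_run: FeatureTrack, percentile: float = 90.0
) -> ClassifierModel:
    """Shift the output so the 90th percentile over a non-control run is 0.

    The rule caps the non-control false-activation rate at roughly 10 % of
    samples at threshold 0; the weights are untouched. Requires at least
    30 s of non-control features.
    """
    if nc_run.n_samples < 30 * nc_run.fs:
        raise ValueError("need >= 30 s of non-control data for bias adaptation")
    out, _ = model.apply(nc_run)
    out = out[nc_run.warmup_samples :]  # the moving-average fill is not data
    q = float(np.percentile(out, percentile))
    return replace(model, out_shift=model.out_shift - q)
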