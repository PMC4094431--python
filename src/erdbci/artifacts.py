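"""Two-stage trial screening and real-time artifact detection.

Calibration-time screening works per trial in two steps: (1) thresholding
amplitude, kurtosis and sample probability of the band-filtered EEG against
the running trial history, and (2) rejecting trials whose trial-averaged
band-power features are leave-one-out outliers within their class.

Online detection whitens the bipolar EEG with the inverse transfer function
of an autoregressive model of order 11 fitted to artifact-free trials and
thresholds the residual; a raised flag is held for 0.5 s past offset,
mirroring the yellow-dot display rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .signals import EEGSegment

AMP_MAX_DEFAULT = 100.0  # uV, peak screening threshold
Z_MAX_DEFAULT = 5.0  # z-score threshold for kurtosis / probability statistics
AR_ORDER = 11
RESIDUAL_PERCENTILE = 99.0
FLAG_HOLD_SECONDS = 0.5


@dataclass(frozen=True)
class ArtifactVerdict:
    """Outcome of trial screening; ``clean`` iff no reason was raised."""

    reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        allowed = {"amplitude", "kurtosis", "probability", "feature_outlier"}
        if not set(self.reasons) <= allowed:
            raise ValueError(f"unknown reasons {set(self.reasons) - allowed}")

    @property
    def clean(self) -> bool:
        return not self.reasons


def _trial_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel (kurtosis, mean, std) of one epoch."""
    kurt = stats.kurtosis(data, axis=0, fisher=True, bias=True)
    return kurt, data.mean(axis=0), data.std(axis=0)


def _mean_loglik(data: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Per-channel mean Gaussian log-likelihood of epoch samples."""
    sd = np.maximum(sd, 1e-12)
    z = (data - mu) / sd
    return (-0.5 * z**2 - np.log(sd) - 0.5 * np.log(2 * np.pi)).mean(axis=0)


def screen_trial_stats(
    trial_eeg: EEGSegment,
    history: list[EEGSegment],
    amp_max: float = AMP_MAX_DEFAULT,
    z_max: float = Z_MAX_DEFAULT,
) -> ArtifactVerdict:
    """Statistics-thresholding screen of one band-filtered trial epoch.

    ``amplitude`` flags any sample beyond ``amp_max``. With at least four
    historical trials, per-channel kurtosis and mean log-likelihood (under a
    Gaussian fitted to the pooled history of that channel) are z-scored
    against the history trials' own statistics and thresholded at ``z_max``.
    Because mean and spread of the reference statistics are *estimated* from
    few trials, the raw z of a clean trial is t-distributed, not normal; the
    cut is therefore placed at the Student-t quantile with ``len(history)-1``
    degrees of freedom matching the normal tail probability of ``z_max``, so
    the intended false-rejection rate holds at every history size. With a
    shorter history only the amplitude criterion applies.
    """
    if trial_eeg.n_samples == 0:
        raise ValueError("empty epoch")
    reasons: set[str] = set()
    if np.any(np.abs(trial_eeg.data) > amp_max):
        reasons.add("amplitude")
    if len(history) >= 4:
        tail = stats.norm.sf(z_max)
        cut = float(stats.t.isf(tail, df=len(history) - 1))
        hist_kurt = np.array([_trial_stats(h.data)[0] for h in history])
        pooled = np.concatenate([h.data for h in history], axis=0)
        mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
        hist_ll = np.array([_mean_loglik(h.data, mu, sd) for h in history])

        trial_kurt = _trial_stats(trial_eeg.data)[0]
        trial_ll = _mean_loglik(trial_eeg.data, mu, sd)

        for name, trial_stat, hist_stat in (
            ("kurtosis", trial_kurt, hist_kurt),
            ("probability", trial_ll, hist_ll),
        ):
            spread = hist_stat.std(axis=0, ddof=1)
            spread = np.maximum(spread, 1e-12)
            z = (trial_stat - hist_stat.mean(axis=0)) / spread
            if np.any(np.abs(z) > cut):
                reasons.add(name)
    return ArtifactVerdict(frozenset(reasons))


def reject_feature_outliers(
    features: np.ndarray,
    labels: np.ndarray,
    k: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out outlier rejection on trial-averaged features.

    A trial is rejected when any of its features lies outside
    mean +/- ``k``*SD of the *remaining* trials of the same class. Returns
    (kept_indices, rejected_indices) into the input order. Zero spread among
    the remaining trials never rejects (identical trials are all kept).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValueError("features must be (n_trials, n_features)")
    rejected = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 6:
            raise ValueError(f"need >= 6 trials per class, got {idx.size} for {cls!r}")
        for i in idx:
            rest = features[idx[idx != i]]
            m = rest.mean(axis=0)
            sd = rest.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore"):
                out = np.abs(features[i] - m) > k * sd
            out &= sd > 0
            if np.any(out):
                rejected.append(i)
    rejected_arr = np.array(sorted(rejected), dtype=int)
    kept = np.setdiff1d(np.arange(len(labels)), rejected_arr)
    if kept.size == 0:
        raise ValueError("all trials rejected as outliers; data unusable")
    return kept, rejected_arr


@dataclass
class ARModel:
    """Per-channel AR(11) model with residual thresholds for online detection."""

    coeffs: np.ndarray  # (n_channels, order)
    residual_threshold: np.ndarray  # (n_channels,), uV
    fs: float = 256.0
    order: int = AR_ORDER

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        self.residual_threshold = np.atleast_1d(
            np.asarray(self.residual_threshold, dtype=float)
        )
        if self.coeffs.shape[1] != self.order:
            raise ValueError(f"expected order {self.order}, got {self.coeffs.shape[1]}")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    def is_stable(self) -> bool:
        for a in self.coeffs:
            roots = np.roots(np.concatenate([[1.0], -a]))
            if np.any(np.abs(roots) >= 1.0):
                return False
        return True


def _ar_lstsq(segments: list[np.ndarray], order: int) -> np.ndarray:
    """Least-squares AR fit for one channel; rows never straddle segments."""
    rows, targets = [], []
    for x in segments:
        if len(x) <= order:
            continue
        # lagged design: column j holds x[t-1-j]
        n = len(x) - order
        design = np.column_stack([x[order - 1 - j : order - 1 - j + n] for j in range(order)])
        rows.append(design)
        targets.append(x[order:])
    if not rows:
        raise ValueError("not enough data for AR fit")
    X = np.vstack(rows)
    y = np.concatenate(targets)
    a, *_ = np.linalg.lstsq(X, y, rcond=None)
    return a


def _ar_residuals(x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Whitened residual e_t = x_t - sum_i a_i x_{t-i} (inverse AR filter)."""
    b = np.concatenate([[1.0], -a])
    return signal.lfilter(b, [1.0], x)


def fit_ar(
    clean_epochs: list[EEGSegment],
    order: int = AR_ORDER,
    threshold_percentile: float = RESIDUAL_PERCENTILE,
) -> ARModel:
    """Fit per-channel AR models on artifact-free epochs.

    Coefficients come from least squares on the lagged design, pooling all
    epochs (no regression row straddles an epoch boundary). The residual
    threshold per channel is the ``threshold_percentile`` of absolute
    training residuals, which fixes the training false-flag rate by
    construction.
    """
    if not clean_epochs:
        raise ValueError("no clean epochs provided")
    fs = clean_epochs[0].fs
    n_ch = clean_epochs[0].data.shape[1]
    total = sum(e.n_samples for e in clean_epochs)
    if total < 10 * fs:
        raise ValueError("need at least 10 s of clean EEG per channel")
    coeffs = np.empty((n_ch, order))
    thresholds = np.empty(n_ch)
    for c in range(n_ch):
        xs = [e.data[:, c] for e in clean_epochs]
        a = _ar_lstsq(xs, order)
        coeffs[c] = a
        resid = np.concatenate([_ar_residuals(x, a)[order:] for x in xs])
        thresholds[c] = np.percentile(np.abs(resid), threshold_percentile)
    model = ARModel(coeffs, thresholds, fs=fs, order=order)
    if not model.is_stable():
        raise ValueError("unstable AR fit; provide a longer clean window")
    return model


class OnlineArtifactDetector:
    """Streaming inverse-AR residual thresholding with display hold.

    A sample is flagged when the whitened residual magnitude exceeds the
    per-channel threshold on any channel; the flag stays raised for
    ``hold`` seconds after the last raw exceedance.
    """

    def __init__(self, model: ARModel, hold: float = FLAG_HOLD_SECONDS):
        self.model = model
        self.hold_samples = int(round(hold * model.fs))
        b = np.concatenate([[1.0], -model.coeffs[0]])
        self._bs = [np.concatenate([[1.0], -a]) for a in model.coeffs]
        self._zi = [np.zeros(len(b) - 1) for _ in range(model.n_channels)]
        self._hold_left = 0

    def process(self, seg: EEGSegment) -> np.ndarray:
        if abs(seg.fs - self.model.fs) > 1e-9:
            raise ValueError(f"stream fs {seg.fs} != model fs {self.model.fs}")
        if seg.data.shape[1] != self.model.n_channels:
            raise ValueError("channel count mismatch with AR model")
        raw = np.zeros(seg.n_samples, dtype=bool)
        for c in range(self.model.n_channels):
            e, self._zi[c] = signal.lfilter(
                self._bs[c], [1.0], seg.data[:, c], zi=self._zi[c]
            )
            raw |= np.abs(e) > self.model.residual_threshold[c]
        flags = np.zeros(seg.n_samples, dtype=bool)
        hold = self._hold_left
        for t in range(seg.n_samples):
            if raw[t]:
                hold = self.hold_samples
                flags[t] = True
            elif hold > 0:
                flags[t] = True
                hold -= 1
        self._hold_left = hold
        return flags


def detect_artifact_online(
    stream: EEGSegment, model: ARModel, hold: float = FLAG_HOLD_SECONDS
) -> np.ndarray:
    """One-shot wrapper around :class:`OnlineArtifactDetector`."""
    return OnlineArtifactDetector(model, hold=hold).process(stream)
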