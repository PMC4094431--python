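"""EEG containers, causal preprocessing and logarithmic band-power features.

Everything here is strictly causal (online-compatible): IIR filters applied
forward only, with explicit filter state so a stream processed block by block
is bit-identical to the same stream processed in one call.

The feature chain mirrors a classic sensorimotor-rhythm BCI front end:
bipolar derivation over the hand/foot motor areas, band-pass to the mu
(9-13 Hz) and beta (16-26 Hz) bands, squaring, a 1 s causal moving average,
and a natural logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

FS_DEFAULT = 256.0

#: canonical montage: (anterior, posterior) electrode per bipolar derivation
DEFAULT_DERIVATIONS: tuple[tuple[str, str], ...] = (
    ("FC3", "CP3"),
    ("FCz", "CPz"),
    ("FC4", "CP4"),
)

#: bipolar channel name for each (anterior, posterior) pair
DERIVATION_NAMES = {("FC3", "CP3"): "C3", ("FCz", "CPz"): "Cz", ("FC4", "CP4"): "C4"}

DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((9.0, 13.0), (16.0, 26.0))
DEFAULT_BAND_NAMES: tuple[str, ...] = ("mu", "beta")

_POWER_FLOOR = 1e-20  # uV^2; keeps log() finite on silent input


@dataclass
class EEGSegment:
    """A block of multichannel EEG.

    data
        ``(n_samples, n_channels)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        10/20 electrode names (or bipolar derivation names), unique.
    t0
        Start time of the block in seconds since session start.
    """

    data: np.ndarray
    fs: float = FS_DEFAULT
    channel_labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None
        return self.data[:, idx]


@dataclass(frozen=True)
class BandPowerConfig:
    """Configuration of the band-power feature extractor.

    Exactly ``len(derivations) * len(bands)`` features are produced; with the
    defaults that is the canonical six: (C3, Cz, C4) x (mu, beta).
    """

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    band_names: tuple[str, ...] = DEFAULT_BAND_NAMES
    avg_window: float = 1.0
    derivations: tuple[tuple[str, str], ...] = DEFAULT_DERIVATIONS

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must have low < high")
        if len(self.band_names) != len(self.bands):
            raise ValueError("one name per band required")
        if self.avg_window <= 0:
            raise ValueError("avg_window must be positive")

    @property
    def derivation_names(self) -> list[str]:
        return [DERIVATION_NAMES.get(pair, f"{pair[0]}-{pair[1]}") for pair in self.derivations]

    @property
    def feature_ids(self) -> list[tuple[str, str]]:
        """Feature identifiers in canonical order: band-major, derivation-minor.

        Defaults: (C3, mu), (Cz, mu), (C4, mu), (C3, beta), (Cz, beta), (C4, beta).
        """
        return [(d, b) for b in self.band_names for d in self.derivation_names]


@dataclass
class FeatureTrack:
    """Per-sample logarithmic band-power features, one column per feature."""

    values: np.ndarray  # (n_samples, n_features), log(uV^2)
    feature_ids: list[tuple[str, str]]
    fs: float = FS_DEFAULT
    t0: float = 0.0
    warmup_samples: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_ids):
            raise ValueError("values must be (n_samples, n_features)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, feature_id: tuple[str, str]) -> np.ndarray:
        fid = tuple(feature_id)
        try:
            idx = self.feature_ids.index(fid)  # type: ignore[arg-type]
        except ValueError:
            raise KeyError(f"feature {fid!r} not in track") from None
        return self.values[:, idx]

    def slice_seconds(self, start: float, stop: float) -> "FeatureTrack":
        """Half-open time slice [start, stop) relative to t0."""
        i0 = int(round(start * self.fs))
        i1 = int(round(stop * self.fs))
        return FeatureTrack(
            self.values[i0:i1], list(self.feature_ids), self.fs, self.t0 + start, 0
        )


# ---------------------------------------------------------------------------
# causal filters


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _notch_ba(freq: float, fs: float, q: float = 30.0):
    return signal.iirnotch(freq, q, fs=fs)


class StreamFilter:
    """Causal SOS filter bank applied per channel with carried state."""

    def __init__(self, sos: np.ndarray, n_channels: int):
        self.sos = sos
        self.zi = np.zeros((sos.shape[0], 2, n_channels))

    def process(self, x: np.ndarray) -> np.ndarray:
        y, self.zi = signal.sosfilt(self.sos, x, axis=0, zi=self.zi)
        return y


class MovingAverage:
    """Causal rectangular moving average with carried state (FIR lfilter)."""

    def __init__(self, n_taps: int, n_channels: int):
        self.b = np.full(n_taps, 1.0 / n_taps)
        self.zi = np.zeros((n_taps - 1, n_channels))

    def process(self, x: np.ndarray) -> np.ndarray:
        y, self.zi = signal.lfilter(self.b, [1.0], x, axis=0, zi=self.zi)
        return y


def preprocess(seg: EEGSegment, state: dict | None = None) -> EEGSegment:
    """Band-pass 0.5-100 Hz and notch 50 Hz, causally.

    Replicates a typical amplifier front end. ``state`` (an initially empty
    dict) carries filter memory across successive blocks of one stream; with
    ``state=None`` the call is stateless (zero initial conditions).
    """
    if abs(seg.fs - FS_DEFAULT) > 1e-9:
        raise ValueError(f"expected fs = {FS_DEFAULT} Hz, got {seg.fs}")
    if not np.all(np.isfinite(seg.data)):
        raise ValueError("non-finite samples in input")
    n_ch = seg.data.shape[1]
    if state is None:
        state = {}
    if "bp" not in state:
        state["bp"] = StreamFilter(_bandpass_sos(0.5, 100.0, seg.fs), n_ch)
        b, a = _notch_ba(50.0, seg.fs)
        state["notch_ba"] = (b, a)
        state["notch_zi"] = np.zeros((max(len(b), len(a)) - 1, n_ch))
    y = state["bp"].process(seg.data)
    b, a = state["notch_ba"]
    y, state["notch_zi"] = signal.lfilter(b, a, y, axis=0, zi=state["notch_zi"])
    return replace(seg, data=y)


def bipolar_derive(seg: EEGSegment, cfg: BandPowerConfig | None = None) -> EEGSegment:
    """Anterior-minus-posterior bipolar derivations (C3, Cz, C4 by default)."""
    cfg = cfg or BandPowerConfig()
    cols = []
    for ant, post in cfg.derivations:
        for lbl in (ant, post):
            if lbl not in seg.channel_labels:
                raise KeyError(f"electrode {lbl!r} missing from segment")
        cols.append(seg.channel(ant) - seg.channel(post))
    return EEGSegment(
        np.column_stack(cols), seg.fs, list(cfg.derivation_names), seg.t0
    )


def log_bandpower(
    seg: EEGSegment, cfg: BandPowerConfig | None = None, state: dict | None = None
) -> FeatureTrack:
    """Per-sample log band-power of each (derivation, band) pair.

    Chain per band: causal Butterworth band-pass -> square -> causal
    rectangular moving average over ``avg_window`` -> natural log. Columns
    follow ``cfg.feature_ids`` order. The first ``avg_window`` of a fresh
    stream is warm-up (the average still fills); ``warmup_samples`` marks it.
    """
    cfg = cfg or BandPowerConfig()
    if not np.all(np.isfinite(seg.data)):
        raise ValueError("non-finite samples in input")
    if list(seg.channel_labels) != list(cfg.derivation_names):
        raise ValueError(
            f"expected bipolar channels {cfg.derivation_names}, got {seg.channel_labels}"
        )
    n_ch = seg.data.shape[1]
    n_taps = int(round(cfg.avg_window * seg.fs))
    fresh = state is None or not state
    if state is None:
        state = {}
    if "bands" not in state:
        state["bands"] = [
            StreamFilter(_bandpass_sos(lo, hi, seg.fs), n_ch) for lo, hi in cfg.bands
        ]
        state["avg"] = [MovingAverage(n_taps, n_ch) for _ in cfg.bands]
    cols = []
    for bf, ma in zip(state["bands"], state["avg"]):
        power = ma.process(bf.process(seg.data) ** 2)
        cols.append(np.log(np.maximum(power, _POWER_FLOOR)))
    values = np.concatenate(cols, axis=1)
    return FeatureTrack(
        values,
        cfg.feature_ids,
        seg.fs,
        seg.t0,
        warmup_samples=n_taps if fresh else 0,
    )


class FeaturePipeline:
    """Streaming preprocess -> bipolar -> log band-power chain.

    Holds all filter state, so feeding a session block by block equals
    feeding it at once. ``reset()`` starts a fresh stream (e.g. a new run).
    """

    def __init__(self, cfg: BandPowerConfig | None = None):
        self.cfg = cfg or BandPowerConfig()
        self.reset()

    def reset(self) -> None:
        self._pre_state: dict = {}
        self._bp_state: dict = {}

    def process(self, seg: EEGSegment) -> tuple[EEGSegment, FeatureTrack]:
        """Return the preprocessed bipolar segment and its feature track."""
        pre = preprocess(seg, state=self._pre_state)
        bip = bipolar_derive(pre, self.cfg)
        feats = log_bandpower(bip, self.cfg, state=self._bp_state)
        return bip, feats
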