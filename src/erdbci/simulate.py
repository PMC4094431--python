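"""Closed-loop synthetic ERD users.

The generator emulates 6-electrode sensorimotor EEG: per-electrode 1/f
(pink) background noise plus a white floor, and narrowband mu/beta rhythms
realized as band-pass-filtered Gaussian noise injected anti-phase into the
anterior/posterior electrode of each bipolar pair (so the bipolar
derivation carries the rhythm at full amplitude). Movement imagery
attenuates the rhythm envelope of the class's (derivation, band) targets by
a configurable fractional power depth after a reaction latency —
event-related desynchronization with a controllable effect size.
Contralateral mapping is fixed: right-hand imagery desynchronizes C3,
left-hand imagery C4.

All randomness flows from one seeded generator; the stream is produced
block-wise with carried filter state, so a session is reproducible
sample-for-sample from (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .classifier import LEFT, NON_CONTROL, RIGHT
from .signals import (
    DEFAULT_BAND_NAMES,
    DEFAULT_BANDS,
    DEFAULT_DERIVATIONS,
    DERIVATION_NAMES,
    EEGSegment,
    _bandpass_sos,
)

ELECTRODES = ["FC3", "CP3", "FCz", "CPz", "FC4", "CP4"]

# Paul Kellet's economy pink-noise IIR (unit-variance white input -> ~1/f)
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def _white_power_gain(b, a=None, sos=None, n: int = 8192) -> float:
    """RMS gain of a filter driven by unit-variance white noise."""
    imp = np.zeros(n)
    imp[0] = 1.0
    h = signal.sosfilt(sos, imp) if sos is not None else signal.lfilter(b, a, imp)
    return float(np.sqrt(np.sum(h**2)))


@dataclass
class SimUserParams:
    """Ground-truth parameters of a simulated user.

    erd_depth maps class label -> {(derivation, band): fractional power
    attenuation in [0, 1)}. Amplitudes are RMS microvolts; ``latency`` is
    the reaction time between a task change and the rhythm responding;
    ``artifact_rate`` is transient events per minute at ``artifact_amp``.
    """

    erd_depth: dict = field(default_factory=dict)
    pink_rms: float = 5.0
    white_rms: float = 1.0
    rhythm_amps: dict = field(
        default_factory=lambda: {
            (d, b): (6.0 if b == "mu" else 5.0)
            for d in ("C3", "Cz", "C4")
            for b in DEFAULT_BAND_NAMES
        }
    )
    latency: float = 0.5
    artifact_rate: float = 0.0
    artifact_amp: float = 400.0

    def __post_init__(self) -> None:
        for cls, feats in self.erd_depth.items():
            if cls not in (LEFT, RIGHT, NON_CONTROL):
                raise ValueError(f"unknown class {cls!r} in erd_depth")
            for fid, depth in feats.items():
                if not 0.0 <= depth < 1.0:
                    raise ValueError(f"depth {depth} for {fid} not in [0, 1)")
        for amp in self.rhythm_amps.values():
            if amp <= 0:
                raise ValueError("rhythm amplitudes must be positive")


def preset(name: str) -> SimUserParams:
    """Named user archetypes used throughout testing.

    ``strong``: deep (50 %) mu ERD over C3 for right-hand imagery;
    ``weak``: the same pattern at 20 % depth; ``null``: no ERD at all;
    ``artifacty``: strong plus frequent high-amplitude transients.
    """
    if name == "strong":
        return SimUserParams(erd_depth={RIGHT: {("C3", "mu"): 0.5}})
    if name == "weak":
        return SimUserParams(erd_depth={RIGHT: {("C3", "mu"): 0.2}})
    if name == "null":
        return SimUserParams(erd_depth={})
    if name == "artifacty":
        return SimUserParams(
            erd_depth={RIGHT: {("C3", "mu"): 0.5}}, artifact_rate=6.0
        )
    raise ValueError(f"unknown preset {name!r}; use strong|weak|null|artifacty")


def respond(scheduled_task: str, mi_class: str | None = None) -> str:
    """The user's mental class given the current instruction.

    Cue-paced: the cue label is followed verbatim. Self-paced: movement
    imagery of the trained hand while the arrow points at the target
    (``"target"``), non-control otherwise (``"non-target"``).
    """
    if scheduled_task in (LEFT, RIGHT, NON_CONTROL):
        return scheduled_task
    if scheduled_task == "target":
        if mi_class is None:
            raise ValueError("mi_class required for target segments")
        return mi_class
    if scheduled_task == "non-target":
        return NON_CONTROL
    raise ValueError(f"unknown task {scheduled_task!r}")


class SimUser:
    """Stateful stream generator for one synthetic user."""

    def __init__(self, params: SimUserParams, seed: int, fs: float = 256.0):
        self.params = params
        self.fs = fs
        # one child stream per noise source: the generated EEG is then
        # independent of how the session chops the stream into blocks
        root = np.random.SeedSequence([int(seed), 0x51D])
        children = root.spawn(2 * len(ELECTRODES) + 6 + 1)
        self.rng = np.random.default_rng(children[-1])  # artifacts etc.
        self._pink_rngs = [np.random.default_rng(c) for c in children[: len(ELECTRODES)]]
        self._white_rngs = [
            np.random.default_rng(c)
            for c in children[len(ELECTRODES) : 2 * len(ELECTRODES)]
        ]
        self._rhythm_rngs = {}
        k = 2 * len(ELECTRODES)
        for pair in DEFAULT_DERIVATIONS:
            for name in DEFAULT_BAND_NAMES:
                self._rhythm_rngs[(DERIVATION_NAMES[pair], name)] = np.random.default_rng(
                    children[k]
                )
                k += 1
        n_el = len(ELECTRODES)
        self._pink_zi = [
            signal.lfilter_zi(_PINK_B, _PINK_A) * 0.0 for _ in range(n_el)
        ]
        self._pink_gain = _white_power_gain(_PINK_B, _PINK_A)
        self._band_sos = {}
        self._band_gain = {}
        self._rhythm_zi = {}
        for (lo, hi), name in zip(DEFAULT_BANDS, DEFAULT_BAND_NAMES):
            sos = _bandpass_sos(lo, hi, fs)
            self._band_sos[name] = sos
            self._band_gain[name] = _white_power_gain(None, sos=sos)
            for pair in DEFAULT_DERIVATIONS:
                deriv = DERIVATION_NAMES[pair]
                self._rhythm_zi[(deriv, name)] = np.zeros((sos.shape[0], 2))
        self._latency_samples = int(round(params.latency * fs))
        self._class_tail = [NON_CONTROL] * self._latency_samples
        self.t = 0.0

    # -- stream -----------------------------------------------------------
    def _effective_classes(self, scheduled: np.ndarray) -> np.ndarray:
        """Delay scheduled classes by the reaction latency, with memory."""
        if self._latency_samples == 0:
            return scheduled
        joined = np.concatenate([np.array(self._class_tail), scheduled])
        self._class_tail = list(joined[len(joined) - self._latency_samples :])
        return joined[: len(scheduled)]

    def generate(self, scheduled_classes: np.ndarray) -> EEGSegment:
        """Generate the next block; one scheduled class label per sample."""
        scheduled = np.asarray(scheduled_classes)
        n = len(scheduled)
        effective = self._effective_classes(scheduled)
        data = np.empty((n, len(ELECTRODES)))
        for i in range(len(ELECTRODES)):
            white = self._pink_rngs[i].standard_normal(n)
            pink, self._pink_zi[i] = signal.lfilter(
                _PINK_B, _PINK_A, white, zi=self._pink_zi[i]
            )
            pink *= self.params.pink_rms / self._pink_gain
            data[:, i] = pink + self.params.white_rms * self._white_rngs[i].standard_normal(n)

        # per-class envelope gain per feature, cached over the label alphabet
        uniq = np.unique(effective)
        for pair in DEFAULT_DERIVATIONS:
            deriv = DERIVATION_NAMES[pair]
            i_ant = ELECTRODES.index(pair[0])
            i_post = ELECTRODES.index(pair[1])
            for name in DEFAULT_BAND_NAMES:
                amp = self.params.rhythm_amps[(deriv, name)]
                raw = self._rhythm_rngs[(deriv, name)].standard_normal(n)
                narrow, self._rhythm_zi[(deriv, name)] = signal.sosfilt(
                    self._band_sos[name], raw, zi=self._rhythm_zi[(deriv, name)]
                )
                narrow *= amp / self._band_gain[name]
                env = np.ones(n)
                for cls in uniq:
                    depth = self.params.erd_depth.get(cls, {}).get((deriv, name), 0.0)
                    if depth > 0.0:
                        env[effective == cls] = np.sqrt(1.0 - depth)
                rhythm = narrow * env
                data[:, i_ant] += 0.5 * rhythm
                data[:, i_post] -= 0.5 * rhythm
        seg = EEGSegment(data, self.fs, list(ELECTRODES), self.t)
        self.t += n / self.fs
        return seg

    def generate_constant(self, label: str, n_samples: int) -> EEGSegment:
        return self.generate(np.full(n_samples, label, dtype=object))

    def reset_stream(self) -> None:
        """Start a fresh recording run (filter memory cleared, time kept)."""
        for zi in self._pink_zi:
            zi[:] = 0.0
        for zi in self._rhythm_zi.values():
            zi[:] = 0.0
        self._class_tail = [NON_CONTROL] * self._latency_samples


def inject_artifacts(
    seg: EEGSegment,
    params: SimUserParams,
    rng: np.random.Generator,
) -> tuple[EEGSegment, list[dict]]:
    """Add Poisson-timed broadband transients; return ground-truth events.

    Each event is a Hann-windowed bump of ``artifact_amp`` microvolts,
    0.2-0.5 s long, on one random electrode. The returned events carry exact
    onsets for detector-latency tests.
    """
    if params.artifact_rate < 0:
        raise ValueError("artifact_rate must be >= 0")
    if params.artifact_rate == 0:
        return seg, []
    duration_min = seg.duration / 60.0
    n_events = rng.poisson(params.artifact_rate * duration_min)
    data = seg.data.copy()
    events = []
    for _ in range(n_events):
        dur = rng.uniform(0.2, 0.5)
        n_dur = int(round(dur * seg.fs))
        if n_dur >= seg.n_samples:
            continue
        start = rng.integers(0, seg.n_samples - n_dur)
        ch = int(rng.integers(0, data.shape[1]))
        data[start : start + n_dur, ch] += params.artifact_amp * np.hanning(n_dur)
        events.append(
            {
                "t_onset": seg.t0 + start / seg.fs,
                "duration": n_dur / seg.fs,
                "channel": seg.channel_labels[ch],
                "amplitude": params.artifact_amp,
            }
        )
    events.sort(key=lambda e: e["t_onset"])
    return EEGSegment(data, seg.fs, list(seg.channel_labels), seg.t0), events
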