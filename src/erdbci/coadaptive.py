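"""Cue-guided co-adaptive training session.

Trial structure: fixation cross at 0-2 s, cue at 2 s, sustained imagery (or
relax) until 7 s, then a 2-3 s pause. Four 6-minute runs of 36 trials each
(144 trials). The session starts cue-ing three classes (non-control, left,
right); as soon as nine artifact-free trials per class are available it
auto-calibrates, picks the better-classifiable hand, and switches to
two-class trials with continuous positive-only feedback between 3.75 and
7 s. It re-calibrates whenever five new artifact-free TPC accrue, and runs
the AR-residual artifact detector online (yellow-dot events with a 0.5 s
display hold).

Cue "randomness" uses permuted balanced blocks (3 classes initially, 2
online), which guarantees the per-run class balance and a first calibration
within five minutes; fully i.i.d. draws could guarantee neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artifacts import OnlineArtifactDetector, screen_trial_stats
from .classifier import (
    CLASSIFY_START,
    CLASSIFY_STOP,
    LEFT,
    NON_CONTROL,
    RIGHT,
    ClassifierModel,
    Trial,
    TrialStore,
    calibrate,
    select_control_class,
)
from .evaluation import AccuracyCurve, samplewise_accuracy
from .signals import BandPowerConfig, EEGSegment, FeaturePipeline
from .simulate import SimUser, inject_artifacts


@dataclass(frozen=True)
class CoadaptiveConfig:
    n_runs: int = 4
    trials_per_run: int = 36
    run_seconds: float = 360.0  # nominal run length (6 min)
    cross_onset: float = 0.0
    cue_onset: float = 2.0
    imagery_end: float = 7.0
    pause_range: tuple[float, float] = (2.0, 3.0)
    feedback_window: tuple[float, float] = (3.75, 7.0)
    reward_min_match: float = 2.0  # cumulative matched seconds within [3, 7)
    fs: float = 256.0

    @property
    def total_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def nominal_minutes(self) -> float:
        return self.n_runs * self.run_seconds / 60.0


@dataclass(frozen=True)
class ParadigmEvent:
    """One timestamped entry of the session log."""

    t: float
    kind: str  # cue | feedback | artifact_flag | reward | calibration | class_selection | run_start
    payload: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrialSlot:
    run: int
    index_in_run: int
    pause: float


@dataclass
class TrialSchedule:
    """Per-trial timing of a co-adaptive session, reproducible from a seed."""

    slots: list[TrialSlot]
    seed: int
    config: CoadaptiveConfig

    @property
    def total_trials(self) -> int:
        return len(self.slots)

    def trial_duration(self, slot: TrialSlot) -> float:
        return self.config.imagery_end + slot.pause

    @property
    def scheduled_duration(self) -> float:
        """Sum of trial durations (excludes inter-run gaps)."""
        return sum(self.trial_duration(s) for s in self.slots)


def make_schedule(seed: int, config: CoadaptiveConfig | None = None) -> TrialSchedule:
    """Sample the per-trial pauses for all runs; cue labels are drawn live
    (the 3-class to 2-class switch depends on when calibration happens)."""
    config = config or CoadaptiveConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0AD]))
    lo, hi = config.pause_range
    slots = [
        TrialSlot(r, i, float(rng.uniform(lo, hi)))
        for r in range(config.n_runs)
        for i in range(config.trials_per_run)
    ]
    return TrialSchedule(slots, seed, config)


class CueSequencer:
    """Permuted balanced blocks over the currently active class set."""

    def __init__(self, seed: int):
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0E5]))
        self._block: list[str] = []
        self._classes: tuple[str, ...] = (NON_CONTROL, LEFT, RIGHT)

    def set_classes(self, classes) -> None:
        """Switch the active set; the current block is discarded."""
        self._classes = tuple(classes)
        self._block = []

    def next(self) -> str:
        if not self._block:
            block = list(self._classes)
            self.rng.shuffle(block)
            self._block = block
        return self._block.pop()


def feedback_bar(
    pred_label: str,
    true_label: str,
    output: float,
    t: float,
    window: tuple[float, float] = (3.75, 7.0),
    display_max: float = 1.0,
) -> float:
    """Positive-only feedback: bar length within the feedback window.

    Only a prediction matching the cued class extends the bar, in proportion
    to the classifier distance (clipped to the display maximum); otherwise,
    and outside the window, the bar is empty.
    """
    if not window[0] <= t < window[1]:
        return 0.0
    if pred_label != true_label:
        return 0.0
    return float(min(abs(output), display_max))


def reward_rule(match: np.ndarray, fs: float = 256.0, min_match: float = 2.0) -> bool:
    """Smiley iff predicted and cued class match for > ``min_match`` seconds
    cumulatively (not necessarily contiguously) within [3, 7) s."""
    return bool(np.sum(match) / fs > min_match)


@dataclass
class TrialRecord:
    """Bookkeeping for one executed trial."""

    index: int
    run: int
    t_start: float
    label: str
    clean: bool
    reasons: tuple[str, ...]
    online: bool  # part of the two-class feedback phase
    predictions: np.ndarray | None = None  # per-sample labels over [3, 7) s
    outputs: np.ndarray | None = None  # normalized classifier output
    rewarded: bool = False


@dataclass
class CoadaptiveResult:
    events: list[ParadigmEvent]
    model: ClassifierModel | None
    records: list[TrialRecord]
    schedule: TrialSchedule
    config: CoadaptiveConfig
    status: str = "complete"

    @property
    def online_records(self) -> list[TrialRecord]:
        return [r for r in self.records if r.online and r.predictions is not None]

    def accuracy_curve(self) -> AccuracyCurve:
        recs = self.online_records
        if not recs:
            raise ValueError("no online feedback trials recorded")
        preds = np.stack([r.predictions for r in recs])
        labels = np.array([r.label for r in recs])
        t = CLASSIFY_START + np.arange(preds.shape[1]) / self.config.fs
        return samplewise_accuracy(preds, labels, t)

    @property
    def peak_accuracy_percent(self) -> float:
        return self.accuracy_curve().peak_percent

    def first_calibration_time(self) -> float | None:
        for ev in self.events:
            if ev.kind == "calibration":
                return ev.t
        return None


def run_coadaptive_session(
    user: SimUser,
    seed: int,
    config: CoadaptiveConfig | None = None,
    bp_config: BandPowerConfig | None = None,
    stop_after_first_calibration: bool = False,
    screen_history: int = 20,
) -> CoadaptiveResult:
    """Execute the full closed-loop co-adaptive session against a simulated
    user and return the event log, trial records and the final model."""
    config = config or CoadaptiveConfig()
    bp_config = bp_config or BandPowerConfig()
    fs = config.fs
    schedule = make_schedule(seed, config)
    sequencer = CueSequencer(seed)
    pipeline = FeaturePipeline(bp_config)
    store = TrialStore(bp_config.feature_ids)
    history: list[EEGSegment] = []
    events: list[ParadigmEvent] = []
    records: list[TrialRecord] = []
    model: ClassifierModel | None = None
    detector: OnlineArtifactDetector | None = None

    i0 = int(round(CLASSIFY_START * fs))
    i1 = int(round(CLASSIFY_STOP * fs))
    fb0, fb1 = config.feedback_window
    t = 0.0
    current_run = -1

    for trial_idx, slot in enumerate(schedule.slots):
        if slot.run != current_run:
            current_run = slot.run
            pipeline.reset()
            user.reset_stream()
            if model is not None and model.ar is not None:
                detector = OnlineArtifactDetector(model.ar)
            events.append(ParadigmEvent(t, "run_start", {"run": current_run}))

        label = sequencer.next()
        duration = schedule.trial_duration(slot)
        n_total = int(round(duration * fs))
        n_cue = int(round(config.cue_onset * fs))
        n_end = int(round(config.imagery_end * fs))
        scheduled = np.full(n_total, NON_CONTROL, dtype=object)
        scheduled[n_cue:n_end] = label

        seg = user.generate(scheduled)
        seg, artifact_truth = inject_artifacts(seg, user.params, user.rng)
        bip, feats = pipeline.process(seg)

        epoch = EEGSegment(bip.data[:n_end], fs, list(bip.channel_labels), t)
        verdict = screen_trial_stats(epoch, history[-screen_history:])
        history.append(epoch)

        events.append(ParadigmEvent(t + config.cue_onset, "cue", {"class": label}))
        if not verdict.clean:
            events.append(
                ParadigmEvent(
                    t + config.imagery_end,
                    "trial_rejected",
                    {"reasons": sorted(verdict.reasons)},
                )
            )

        record = TrialRecord(
            index=trial_idx,
            run=slot.run,
            t_start=t,
            label=label,
            clean=verdict.clean,
            reasons=tuple(sorted(verdict.reasons)),
            online=model is not None,
        )

        if verdict.clean:
            track = feats.values[i0:i1]
            store.add(
                Trial(
                    label=label,
                    feature_track=track,
                    feature_means=track.mean(axis=0),
                    eeg=epoch,
                )
            )

        if model is not None:
            out, pred = model.apply(feats.values[i0:i1, _feature_index(bp_config, model)])
            record.predictions = pred
            record.outputs = out
            match = pred == label
            record.rewarded = reward_rule(match, fs, config.reward_min_match)
            # bar length logged at 4 Hz to keep the event log tractable
            step = int(fs // 4)
            for k in range(0, len(out), step):
                tk = CLASSIFY_START + k / fs
                if fb0 <= tk < fb1:
                    length = feedback_bar(pred[k], label, out[k], tk, (fb0, fb1))
                    events.append(
                        ParadigmEvent(t + tk, "feedback", {"bar": round(length, 4)})
                    )
            if record.rewarded:
                events.append(
                    ParadigmEvent(t + config.imagery_end, "reward", {"class": label})
                )
            if detector is not None:
                flags = detector.process(seg_bipolar(bip))
                for on, off in _flag_intervals(flags, fs):
                    events.append(
                        ParadigmEvent(
                            t + on, "artifact_flag", {"t_off": round(t + off, 6)}
                        )
                    )
        records.append(record)

        if model is None:
            if store.ready_initial():
                selected = select_control_class(store, fs=fs)
                model = calibrate(store, mi_label=selected, fs=fs)
                assert model is not None
                t_cal = t + duration
                events.append(
                    ParadigmEvent(t_cal, "class_selection", {"class": selected})
                )
                events.append(
                    ParadigmEvent(
                        t_cal,
                        "calibration",
                        {
                            "count": model.calib_count,
                            "feature": list(model.feature_id),
                            "window": model.train_window,
                        },
                    )
                )
                sequencer.set_classes((NON_CONTROL, selected))
                if model.ar is not None:
                    detector = OnlineArtifactDetector(model.ar)
                if stop_after_first_calibration:
                    t += duration
                    return CoadaptiveResult(
                        events, model, records, schedule, config, status="truncated"
                    )
        else:
            new_model = calibrate(store, previous=model, fs=fs)
            if new_model is not None:
                model = new_model
                events.append(
                    ParadigmEvent(
                        t + duration,
                        "calibration",
                        {
                            "count": model.calib_count,
                            "feature": list(model.feature_id),
                            "window": model.train_window,
                        },
                    )
                )
                if model.ar is not None:
                    detector = OnlineArtifactDetector(model.ar)
        t += duration

    return CoadaptiveResult(events, model, records, schedule, config)


def _feature_index(bp_config: BandPowerConfig, model: ClassifierModel) -> int:
    return bp_config.feature_ids.index(tuple(model.feature_id))


def seg_bipolar(bip: EEGSegment) -> EEGSegment:
    return bip


def _flag_intervals(flags: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """(onset, offset) seconds of contiguous True runs."""
    if not flags.any():
        return []
    edges = np.diff(flags.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        stops.append(len(flags))
    return [(a / fs, b / fs) for a, b in zip(starts, stops)]
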