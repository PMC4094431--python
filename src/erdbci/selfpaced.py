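"""Self-paced (asynchronous) brain-switch training paradigm.

An arrow rotates over six circular segments, four seconds per segment. The
user rests (non-control) until the arrow reaches the announced target
segment, then performs the trained movement imagery. The classifier output
drives the arrow length in target segments; in non-target segments sham
feedback (sub-threshold Gaussian length) is displayed so errors are never
shown — but real false-positive activations are still logged for
evaluation. An activation fires for every uninterrupted full second the
output stays above the 0.5 threshold (so a segment-long span scores the
maximum of four points); a scored target freezes the arrow for a 3 s
refractory period. Targets are scheduled uniformly two to five segments
clockwise after the previous one.

The first 60 s run contains no targets and only adapts the classifier bias;
the two 420 s runs are scored into TP/FP/TN/FN segment outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import ClassifierModel, adapt_bias
from .coadaptive import ParadigmEvent
from .evaluation import ConfusionCounts, balanced_accuracy, selfpaced_chance_threshold
from .signals import BandPowerConfig, FeaturePipeline
from .simulate import SimUser, respond


@dataclass(frozen=True)
class SelfPacedConfig:
    n_segments: int = 6
    seconds_per_segment: float = 4.0
    activation_threshold: float = 0.5
    dwell: float = 1.0
    refractory: float = 3.0
    run_lengths: tuple[float, ...] = (60.0, 420.0, 420.0)
    target_offset_range: tuple[int, int] = (2, 5)  # inclusive, segments clockwise
    sham_mean: float = 0.25
    sham_sd: float = 0.08
    sham_max: float = 0.45
    fs: float = 256.0

    def __post_init__(self) -> None:
        if self.n_segments < 6:
            raise ValueError("need at least 6 segments")
        if not 0.0 < self.activation_threshold < 1.0:
            raise ValueError("activation threshold must be in (0, 1)")
        if min(self.seconds_per_segment, self.dwell, self.refractory) <= 0:
            raise ValueError("durations must be positive")
        if self.sham_max >= self.activation_threshold:
            raise ValueError("sham display must stay below the activation threshold")


@dataclass
class SegmentRecord:
    """Outcome of one arrow pass over one segment."""

    index: int
    run: int
    t_start: float
    is_target: bool
    activations: int
    points: int
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if self.points > 4:
            raise ValueError("points cannot exceed 4")
        if not self.is_target and self.points != 0:
            raise ValueError("non-target segments score no points")


def next_target(
    current_position: int, rng: np.random.Generator, cfg: SelfPacedConfig | None = None
) -> int:
    """Next target segment: uniformly 2-5 segments clockwise from here."""
    cfg = cfg or SelfPacedConfig()
    lo, hi = cfg.target_offset_range
    offset = int(rng.integers(lo, hi + 1))
    return (current_position + offset) % cfg.n_segments


def step_ui(
    t: float,
    output: float,
    is_target: bool,
    cfg: SelfPacedConfig,
    rng: np.random.Generator,
) -> tuple[float, str]:
    """Displayed arrow (length, color-state) for one sample.

    Target segments show real feedback: length proportional to the positive
    classifier output (clipped to 1), red above the activation threshold,
    blue otherwise. Non-target segments show sham feedback clipped safely
    below threshold, so false positives are invisible to the user.
    """
    if is_target:
        length = float(np.clip(max(output, 0.0), 0.0, 1.0))
        state = "red" if length > cfg.activation_threshold else "blue"
        return length, state
    length = float(np.clip(rng.normal(cfg.sham_mean, cfg.sham_sd), 0.0, cfg.sham_max))
    return length, "blue"


def detect_activation(
    outputs: np.ndarray,
    cfg: SelfPacedConfig | None = None,
    fs: float | None = None,
) -> np.ndarray:
    """Sample indices of activation events in an output stream.

    Every uninterrupted full dwell period above threshold yields one event,
    so a span of length L seconds produces floor(L / dwell) consecutive
    events. The dwell clock resets wherever the stream is cut (callers score
    per segment, which resets it at segment boundaries).
    """
    cfg = cfg or SelfPacedConfig()
    fs = fs or cfg.fs
    dwell_n = int(round(cfg.dwell * fs))
    above = np.asarray(outputs) > cfg.activation_threshold
    events = []
    run_start = None
    for i, a in enumerate(np.append(above, False)):
        if a and run_start is None:
            run_start = i
        elif not a and run_start is not None:
            length = i - run_start
            for k in range(length // dwell_n):
                events.append(run_start + (k + 1) * dwell_n - 1)
            run_start = None
    return np.array(events, dtype=int)


def score_segment(
    index: int, run: int, t_start: float, n_activations: int, is_target: bool
) -> SegmentRecord:
    """Fold a segment's activation count into TP/FP/TN/FN and points."""
    if is_target:
        return SegmentRecord(
            index, run, t_start, True,
            activations=n_activations,
            points=min(n_activations, 4),
            tp=n_activations, fp=0, tn=0, fn=int(n_activations == 0),
        )
    return SegmentRecord(
        index, run, t_start, False,
        activations=n_activations,
        points=0,
        tp=0, fp=n_activations, tn=int(n_activations == 0), fn=0,
    )


@dataclass
class SelfPacedResult:
    events: list[ParadigmEvent]
    records: list[SegmentRecord]
    model: ClassifierModel  # bias-adapted
    config: SelfPacedConfig
    counts: ConfusionCounts = field(init=False)

    def __post_init__(self) -> None:
        tp = sum(r.tp for r in self.records)
        fp = sum(r.fp for r in self.records)
        tn = sum(r.tn for r in self.records)
        fn = sum(r.fn for r in self.records)
        n = max(len(self.records), 1)
        frac = sum(r.is_target for r in self.records) / n
        self.counts = ConfusionCounts(tp, fp, tn, fn, target_fraction=frac)

    @property
    def n_target_segments(self) -> int:
        return sum(r.is_target for r in self.records)

    @property
    def balanced_accuracy_percent(self) -> float:
        return balanced_accuracy(self.counts)

    @property
    def chance_threshold_percent(self) -> float:
        return selfpaced_chance_threshold(self.n_target_segments)

    @property
    def significant(self) -> bool:
        return self.balanced_accuracy_percent > self.chance_threshold_percent


def run_selfpaced_session(
    user: SimUser,
    model: ClassifierModel,
    seed: int,
    config: SelfPacedConfig | None = None,
    bp_config: BandPowerConfig | None = None,
) -> SelfPacedResult:
    """Run bias adaptation plus two scored runs against a simulated user.

    The classifier handed in is the last one produced by the co-adaptive
    session; its bias is adapted on the first (non-control) run and the
    adapted model is used, unchanged, for the scored runs.
    """
    if model is None:
        raise ValueError("a calibrated classifier model is required")
    cfg = config or SelfPacedConfig()
    bp_config = bp_config or BandPowerConfig()
    fs = cfg.fs
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E1F]))
    pipeline = FeaturePipeline(bp_config)
    events: list[ParadigmEvent] = []
    records: list[SegmentRecord] = []
    mi_class = model.selected_class

    # run 1: non-control only; adapt the bias
    user.reset_stream()
    pipeline.reset()
    n_adapt = int(round(cfg.run_lengths[0] * fs))
    seg = user.generate_constant("non-control", n_adapt)
    _, feats = pipeline.process(seg)
    model = adapt_bias(model, feats)
    events.append(
        ParadigmEvent(cfg.run_lengths[0], "bias_adaptation", {"shift": model.out_shift})
    )

    seg_n = int(round(cfg.seconds_per_segment * fs))
    t_global = cfg.run_lengths[0]
    seg_index = 0
    for run_no, run_len in enumerate(cfg.run_lengths[1:], start=1):
        user.reset_stream()
        pipeline.reset()
        t_run = 0.0
        position = int(rng.integers(0, cfg.n_segments))
        target = next_target(position, rng, cfg)
        while t_run + cfg.seconds_per_segment <= run_len:
            position = (position + 1) % cfg.n_segments
            is_target = bool(position == target)
            task = "target" if is_target else "non-target"
            scheduled = np.full(seg_n, respond(task, mi_class), dtype=object)
            eeg = user.generate(scheduled)
            _, feats = pipeline.process(eeg)
            out, _ = model.apply(feats)
            act_idx = detect_activation(out, cfg, fs)
            rec = score_segment(seg_index, run_no, t_global + t_run, len(act_idx), is_target)
            records.append(rec)
            for i in act_idx:
                events.append(
                    ParadigmEvent(
                        t_global + t_run + (i + 1) / fs,
                        "activation",
                        {"segment": seg_index, "target": is_target},
                    )
                )
            # displayed feedback, logged at segment resolution
            sham_rng = rng
            mid_len, mid_state = step_ui(
                t_global + t_run, float(out[seg_n // 2]), is_target, cfg, sham_rng
            )
            events.append(
                ParadigmEvent(
                    t_global + t_run,
                    "segment",
                    {
                        "segment": seg_index,
                        "target": is_target,
                        "points": rec.points,
                        "arrow": round(mid_len, 4),
                        "state": mid_state,
                    },
                )
            )
            t_run += cfg.seconds_per_segment
            if is_target:
                if rec.points >= 1:
                    # scored target: arrow freezes, points displayed
                    events.append(
                        ParadigmEvent(
                            t_global + t_run, "refractory", {"points": rec.points}
                        )
                    )
                    n_refr = int(round(cfg.refractory * fs))
                    eeg = user.generate_constant("non-control", n_refr)
                    pipeline.process(eeg)  # keep filter state warm, no scoring
                    t_run += cfg.refractory
                target = next_target(int(position), rng, cfg)
            seg_index += 1
        t_global += run_len
    return SelfPacedResult(events, records, model, cfg)
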