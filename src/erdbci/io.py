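"""File formats: EDF signals, session logs (CSV/JSON), experiment configs.

EDF reading goes through MNE. Writing uses a small EDF writer implemented
here (16-bit EDF with one-second data records), sufficient for round-
tripping synthetic sessions; physical units are microvolts throughout.

Session logs serialize the paradigm event stream with a stable column order
and 6-decimal fixed-point times, in both CSV and JSON dialects.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coadaptive import CoadaptiveConfig, ParadigmEvent, TrialRecord
from .selfpaced import SegmentRecord, SelfPacedConfig
from .signals import FS_DEFAULT, BandPowerConfig, EEGSegment
from .simulate import SimUserParams

# ---------------------------------------------------------------------------
# EDF


def _pad_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, seg: EEGSegment) -> None:
    """Write a segment as 16-bit EDF with 1 s data records (zero-padded)."""
    path = Path(path)
    fs = seg.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record (1 s records)
    n_sig = seg.data.shape[1]
    n_rec = math.ceil(seg.n_samples / spr)
    data = np.zeros((n_rec * spr, n_sig))
    data[: seg.n_samples] = seg.data

    phys_max = max(float(np.max(np.abs(data))) * 1.0001, 1.0)
    # the header field is 8 ASCII chars; scale with the exact encoded value
    phys_max = float(f"{phys_max:.6g}"[:8])
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    header = b""
    header += _pad_field("0", 8)
    header += _pad_field("synthetic", 80)
    header += _pad_field("erdbci session", 80)
    header += _pad_field("01.01.00", 8)
    header += _pad_field("00.00.00", 8)
    header += _pad_field(256 * (1 + n_sig), 8)
    header += _pad_field("", 44)
    header += _pad_field(n_rec, 8)
    header += _pad_field("1", 8)
    header += _pad_field(n_sig, 4)
    for lbl in seg.channel_labels:
        header += _pad_field(lbl, 16)
    header += b"".join(_pad_field("", 80) for _ in range(n_sig))
    header += b"".join(_pad_field("uV", 8) for _ in range(n_sig))
    header += b"".join(_pad_field(f"{phys_min:.6g}"[:8], 8) for _ in range(n_sig))
    header += b"".join(_pad_field(f"{phys_max:.6g}"[:8], 8) for _ in range(n_sig))
    header += b"".join(_pad_field(dig_min, 8) for _ in range(n_sig))
    header += b"".join(_pad_field(dig_max, 8) for _ in range(n_sig))
    header += b"".join(_pad_field("", 80) for _ in range(n_sig))
    header += b"".join(_pad_field(spr, 8) for _ in range(n_sig))
    header += b"".join(_pad_field("", 32) for _ in range(n_sig))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[r * spr : (r + 1) * spr]
            fh.write(block.T.tobytes())  # signal-major within each record


def read_edf(path: str | Path) -> EEGSegment:
    """Load an EDF file into an :class:`EEGSegment` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # MNE loads volts
    fs = float(raw.info["sfreq"])
    return EEGSegment(data, fs, list(raw.ch_names), 0.0)


def require_fs(seg: EEGSegment, fs: float = FS_DEFAULT) -> EEGSegment:
    if abs(seg.fs - fs) > 1e-6:
        raise ValueError(f"pipeline requires {fs} Hz data, file has {seg.fs} Hz")
    return seg


# ---------------------------------------------------------------------------
# session logs

LOG_COLUMNS = ["t", "kind", "payload"]


def events_to_frame(events: list[ParadigmEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": [f"{ev.t:.6f}" for ev in events],
            "kind": [ev.kind for ev in events],
            "payload": [json.dumps(ev.payload, sort_keys=True) for ev in events],
        }
    )


def write_session_log(path: str | Path, events: list[ParadigmEvent]) -> None:
    path = Path(path)
    frame = events_to_frame(events)
    if path.suffix == ".json":
        records = [
            {"t": float(t), "kind": k, "payload": json.loads(p)}
            for t, k, p in frame.itertuples(index=False)
        ]
        path.write_text(json.dumps(records, indent=1))
    else:
        frame.to_csv(path, index=False)


def read_session_log(path: str | Path) -> list[ParadigmEvent]:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
        return [ParadigmEvent(float(r["t"]), r["kind"], r["payload"]) for r in records]
    frame = pd.read_csv(path, dtype={"t": float, "kind": str, "payload": str})
    unknown = [c for c in frame.columns if c not in LOG_COLUMNS]
    if unknown or list(frame.columns) != LOG_COLUMNS:
        raise ValueError(f"unexpected session-log columns: {unknown or list(frame.columns)}")
    return [
        ParadigmEvent(float(r.t), r.kind, json.loads(r.payload))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# trial / segment tables


def trials_to_frame(records: list[TrialRecord], selected_class: str | None) -> pd.DataFrame:
    rows = []
    for r in records:
        pred = ""
        outs = ""
        if r.predictions is not None:
            pred = "".join("1" if p == selected_class else "0" for p in r.predictions)
            outs = ";".join(f"{o:.4f}" for o in r.outputs)
        rows.append(
            {
                "index": r.index,
                "run": r.run,
                "t_start": f"{r.t_start:.6f}",
                "label": r.label,
                "clean": int(r.clean),
                "reasons": "|".join(r.reasons),
                "online": int(r.online),
                "rewarded": int(r.rewarded),
                "selected_class": selected_class or "",
                "predictions": pred,
                "outputs": outs,
            }
        )
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame) -> tuple[list[TrialRecord], str | None]:
    records = []
    selected = None
    for _, row in frame.iterrows():
        sel = str(row["selected_class"]) if str(row["selected_class"]) not in ("", "nan") else None
        selected = selected or sel
        pred = None
        outs = None
        if isinstance(row["predictions"], str) and row["predictions"] and sel:
            pred = np.array([sel if c == "1" else "non-control" for c in row["predictions"]])
            outs = np.array([float(x) for x in str(row["outputs"]).split(";")])
        reasons = str(row["reasons"])
        records.append(
            TrialRecord(
                index=int(row["index"]),
                run=int(row["run"]),
                t_start=float(row["t_start"]),
                label=str(row["label"]),
                clean=bool(int(row["clean"])),
                reasons=tuple(reasons.split("|")) if reasons not in ("", "nan") else (),
                online=bool(int(row["online"])),
                predictions=pred,
                outputs=outs,
                rewarded=bool(int(row["rewarded"])),
            )
        )
    return records, selected


def segments_to_frame(records: list[SegmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "index": r.index,
                "run": r.run,
                "t_start": f"{r.t_start:.6f}",
                "is_target": int(r.is_target),
                "activations": r.activations,
                "points": r.points,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
            }
            for r in records
        ]
    )


def frame_to_segments(frame: pd.DataFrame) -> list[SegmentRecord]:
    return [
        SegmentRecord(
            index=int(r["index"]),
            run=int(r["run"]),
            t_start=float(r["t_start"]),
            is_target=bool(int(r["is_target"])),
            activations=int(r["activations"]),
            points=int(r["points"]),
            tp=int(r["tp"]),
            fp=int(r["fp"]),
            tn=int(r["tn"]),
            fn=int(r["fn"]),
        )
        for _, r in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# experiment configuration


@dataclasses.dataclass
class ExperimentConfig:
    """Bundle of all sub-configurations plus seed and output directory."""

    seed: int = 1
    preset: str = "strong"
    out_dir: str = "."
    bandpower: BandPowerConfig = dataclasses.field(default_factory=BandPowerConfig)
    coadaptive: CoadaptiveConfig = dataclasses.field(default_factory=CoadaptiveConfig)
    selfpaced: SelfPacedConfig = dataclasses.field(default_factory=SelfPacedConfig)
    user: SimUserParams | None = None

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {_key_str(k): plain(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, list):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = {
            "seed": self.seed,
            "preset": self.preset,
            "out_dir": self.out_dir,
            "bandpower": plain(self.bandpower),
            "coadaptive": plain(self.coadaptive),
            "selfpaced": plain(self.selfpaced),
        }
        if self.user is not None:
            d["user"] = plain(self.user)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def tup(seq):
            return tuple(tuple(x) if isinstance(x, list) else x for x in seq)

        bp = d.get("bandpower", {})
        bandpower = BandPowerConfig(
            bands=tup(bp.get("bands", BandPowerConfig().bands)),
            band_names=tuple(bp.get("band_names", BandPowerConfig().band_names)),
            avg_window=bp.get("avg_window", 1.0),
            derivations=tup(bp.get("derivations", BandPowerConfig().derivations)),
        )
        co = dict(d.get("coadaptive", {}))
        if "pause_range" in co:
            co["pause_range"] = tuple(co["pause_range"])
        if "feedback_window" in co:
            co["feedback_window"] = tuple(co["feedback_window"])
        sp = dict(d.get("selfpaced", {}))
        if "run_lengths" in sp:
            sp["run_lengths"] = tuple(sp["run_lengths"])
        if "target_offset_range" in sp:
            sp["target_offset_range"] = tuple(sp["target_offset_range"])
        user = None
        if "user" in d:
            u = dict(d["user"])
            if "erd_depth" in u:
                u["erd_depth"] = {
                    cls: {_key_tuple(k): v for k, v in feats.items()}
                    for cls, feats in u["erd_depth"].items()
                }
            if "rhythm_amps" in u:
                u["rhythm_amps"] = {_key_tuple(k): v for k, v in u["rhythm_amps"].items()}
            user = SimUserParams(**u)
        return cls(
            seed=d.get("seed", 1),
            preset=d.get("preset", "strong"),
            out_dir=d.get("out_dir", "."),
            bandpower=bandpower,
            coadaptive=CoadaptiveConfig(**co),
            selfpaced=SelfPacedConfig(**sp),
            user=user,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _key_str(key) -> str:
    if isinstance(key, tuple):
        return ":".join(str(k) for k in key)
    return str(key)


def _key_tuple(key: str):
    return tuple(key.split(":")) if ":" in key else key
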