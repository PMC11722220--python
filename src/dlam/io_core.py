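"""On-disk formats and shared domain containers.

Recordings travel as flat little-endian int16 sample files with a JSON
sidecar (sampling rate, channel count, per-channel depth, volts-per-count),
the convention used by common extracellular acquisition systems.  Stimulus
schedules, sorted spikes, waveform templates and ROI fluorescence traces are
delimited text tables with headers.  All times are seconds, depths are
micrometres along the probe (increasing = deeper), and voltages are volts
internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DlamError",
    "ValidationError",
    "FormatError",
    "CorruptFileError",
    "RecordingSession",
    "Block",
    "StimulusSchedule",
    "SortedUnit",
    "RoiTraceSet",
    "read_recording",
    "write_recording",
    "read_schedule",
    "write_schedule",
    "read_units",
    "write_units",
    "read_roi_traces",
    "write_roi_traces",
    "read_table",
    "write_table",
]

CONDITIONS = ("monocular", "concordant", "phase_offset", "orthogonal")


class DlamError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DlamError):
    """An input violates a container invariant or precondition."""


class FormatError(DlamError):
    """A file is missing or its metadata is malformed."""


class CorruptFileError(FormatError):
    """File contents disagree with their declared metadata."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class RecordingSession:
    """Multi-channel extracellular recording in volts.

    ``samples`` is channels x time.  ``channel_depths_um`` runs along the
    probe; strictly increasing index = deeper site (laminar probes use a
    uniform 20 um spacing).
    """

    samples: np.ndarray
    fs: float
    channel_depths_um: np.ndarray
    volts_per_count: float
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.volts_per_count <= 0:
            raise ValidationError("volts_per_count must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValidationError("samples must be a channels x time array")
        if self.channel_depths_um.shape[0] != self.samples.shape[0]:
            raise ValidationError("one depth per channel required")
        d = np.diff(self.channel_depths_um)
        if self.samples.shape[0] > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("channel depths must be strictly monotone")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def spacing_um(self) -> float:
        if self.n_channels < 2:
            raise ValidationError("spacing undefined for a single channel")
        d = np.diff(self.channel_depths_um)
        if not np.allclose(d, d[0]):
            raise ValidationError("channel spacing is not uniform")
        return abs(float(d[0]))


@dataclass(frozen=True)
class Block:
    condition: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class StimulusSchedule:
    """Condition blocks, phase-reversal event times, and interblock gaps.

    ``reversal_events[i]`` are the event times (s) inside ``blocks[i]``.
    Interblock intervals default to the gaps between consecutive blocks;
    they are the gray-screen baseline used for all z-scoring and dF/F.
    """

    blocks: list[Block]
    reversal_events: list[np.ndarray]
    interblock_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = [b if isinstance(b, Block) else Block(*b) for b in self.blocks]
        self.reversal_events = [np.asarray(e, dtype=float) for e in self.reversal_events]
        if len(self.reversal_events) != len(self.blocks):
            raise ValidationError("one event list per block required")
        for b in self.blocks:
            if b.end_s <= b.start_s:
                raise ValidationError(f"block {b} has non-positive duration")
        starts = [b.start_s for b in self.blocks]
        order = np.argsort(starts)
        self.blocks = [self.blocks[i] for i in order]
        self.reversal_events = [np.sort(self.reversal_events[i]) for i in order]
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(f"blocks overlap: {a} and {b}")
        for b, ev in zip(self.blocks, self.reversal_events):
            if ev.size and (ev.min() < b.start_s or ev.max() >= b.end_s):
                raise ValidationError(f"event outside its block {b}")
        if not self.interblock_intervals:
            self.interblock_intervals = [
                (a.end_s, b.start_s)
                for a, b in zip(self.blocks, self.blocks[1:])
                if b.start_s > a.end_s
            ]
        for s, e in self.interblock_intervals:
            if e <= s:
                raise ValidationError("interblock interval has non-positive duration")
            for b in self.blocks:
                if s < b.end_s and e > b.start_s:
                    raise ValidationError("interblock interval overlaps a block")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for b in self.blocks:
            if b.condition not in seen:
                seen.append(b.condition)
        return seen

    @property
    def end_s(self) -> float:
        return max(b.end_s for b in self.blocks)

    def blocks_for(self, condition: str) -> list[int]:
        return [i for i, b in enumerate(self.blocks) if b.condition == condition]

    def events_for(self, condition: str) -> np.ndarray:
        idx = self.blocks_for(condition)
        if not idx:
            return np.empty(0)
        return np.concatenate([self.reversal_events[i] for i in idx])

    def n_trials(self, condition: str) -> int:
        return int(self.events_for(condition).size)

    def interblock_mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Boolean mask over a sample axis marking interblock (gray) samples."""
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.interblock_intervals:
            mask[int(round(s * fs)): min(int(round(e * fs)), n_samples)] = True
        return mask

    def block_mask(self, n_samples: int, fs: float, condition: str | None = None) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for b in self.blocks:
            if condition is None or b.condition == condition:
                mask[int(round(b.start_s * fs)): min(int(round(b.end_s * fs)), n_samples)] = True
        return mask


@dataclass
class SortedUnit:
    """A curated single unit: spike times, mean template, depth and class.

    ``depth_um`` is signed relative to the L4 reference (positive =
    superficial).  ``waveform_mv`` is the mean template sampled at
    ``waveform_fs`` (25 kHz by convention).
    """

    unit_id: str
    spike_times_s: np.ndarray
    waveform_mv: np.ndarray
    depth_um: float = 0.0
    cls: str | None = None
    waveform_fs: float = 25_000.0

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        self.waveform_mv = np.asarray(self.waveform_mv, dtype=float)
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if self.cls not in (None, "RS", "FS"):
            raise ValidationError("cls must be RS, FS or None")


@dataclass
class RoiTraceSet:
    """Per-ROI fluorescence and surrounding-neuropil traces with block structure."""

    F: np.ndarray          # (n_rois, n_frames), arbitrary fluorescence units
    F_neuropil: np.ndarray
    frame_rate: float      # Hz, ~14.9 for resonant two-photon
    schedule: StimulusSchedule
    roi_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.F_neuropil = np.atleast_2d(np.asarray(self.F_neuropil, dtype=float))
        if self.frame_rate <= 0:
            raise ValidationError("frame rate must be positive")
        if self.F.shape != self.F_neuropil.shape:
            raise ValidationError("F and F_neuropil must have matching shapes")
        if self.roi_ids is None:
            self.roi_ids = [f"roi{i:04d}" for i in range(self.F.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]


# ---------------------------------------------------------------------------
# recordings: flat int16 + JSON sidecar


def write_recording(session: RecordingSession, path: str | Path) -> None:
    """Write ``<path>.bin`` (int16 LE, channel-interleaved) + ``<path>.json``."""
    base = Path(path).with_suffix("")
    counts = np.round(session.samples / session.volts_per_count)
    if np.any(np.abs(counts) > np.iinfo(np.int16).max):
        raise ValidationError("samples exceed int16 range at this volts_per_count")
    counts.astype("<i2").T.tofile(base.with_suffix(".bin"))  # time-major frames
    meta = {
        "session_id": session.session_id,
        "fs": session.fs,
        "n_channels": session.n_channels,
        "volts_per_count": session.volts_per_count,
        "channel_depths_um": session.channel_depths_um.tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> RecordingSession:
    base = Path(path).with_suffix("")
    binf, sidecar = base.with_suffix(".bin"), base.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    if not binf.exists():
        raise FormatError(f"missing sample file {binf}")
    try:
        meta = json.loads(sidecar.read_text())
        n_channels = int(meta["n_channels"])
        fs = float(meta["fs"])
        vpc = float(meta["volts_per_count"])
        depths = np.asarray(meta["channel_depths_um"], dtype=float)
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    if vpc <= 0:
        raise ValidationError("volts_per_count must be positive")
    if len(depths) != n_channels:
        raise FormatError("sidecar channel count disagrees with depth list")
    raw = np.fromfile(binf, dtype="<i2")
    if raw.size % n_channels:
        raise CorruptFileError(
            f"{binf}: {raw.size} samples not divisible by {n_channels} channels"
        )
    samples = raw.reshape(-1, n_channels).T.astype(float) * vpc
    return RecordingSession(samples, fs, depths, vpc, meta.get("session_id", base.name))


# ---------------------------------------------------------------------------
# tables


def write_table(records: Sequence[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Write homogeneous records as a delimited text table with header.

    Column order is deterministic: the key order of the first record (or the
    explicit ``columns``).  Records with differing key sets are rejected.
    """
    records = list(records)
    if records:
        keys = list(records[0].keys())
        for r in records:
            if list(r.keys()) != keys and set(r.keys()) != set(keys):
                raise ValidationError("records have inconsistent field sets")
        columns = columns or keys
    elif columns is None:
        raise ValidationError("empty record list needs explicit columns")
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing table {path}")
    return pd.read_csv(path)


def write_schedule(schedule: StimulusSchedule, schedule_path: str | Path,
                   events_path: str | Path | None = None) -> None:
    schedule_path = Path(schedule_path)
    events_path = Path(events_path) if events_path else schedule_path.with_name("events.csv")
    write_table(
        [
            {"block_id": i, "condition": b.condition, "start_s": b.start_s, "end_s": b.end_s}
            for i, b in enumerate(schedule.blocks)
        ],
        schedule_path,
        columns=["block_id", "condition", "start_s", "end_s"],
    )
    write_table(
        [
            {"block_id": i, "time_s": t}
            for i, ev in enumerate(schedule.reversal_events)
            for t in ev
        ],
        events_path,
        columns=["block_id", "time_s"],
    )


def read_schedule(schedule_path: str | Path,
                  events_path: str | Path | None = None) -> StimulusSchedule:
    schedule_path = Path(schedule_path)
    events_path = Path(events_path) if events_path else schedule_path.with_name("events.csv")
    bt = read_table(schedule_path)
    for col in ("block_id", "condition", "start_s", "end_s"):
        if col not in bt.columns:
            raise FormatError(f"schedule table missing column {col!r}")
    et = read_table(events_path) if Path(events_path).exists() else pd.DataFrame(
        columns=["block_id", "time_s"])
    blocks, events = [], []
    for _, row in bt.sort_values("start_s").iterrows():
        blocks.append(Block(str(row["condition"]), float(row["start_s"]), float(row["end_s"])))
        ev = et.loc[et["block_id"] == row["block_id"], "time_s"].to_numpy(dtype=float)
        events.append(np.sort(ev))
    return StimulusSchedule(blocks, events)


def write_units(units: Sequence[SortedUnit], spikes_path: str | Path,
                waveforms_path: str | Path | None = None) -> None:
    spikes_path = Path(spikes_path)
    waveforms_path = Path(waveforms_path) if waveforms_path else spikes_path.with_name("waveforms.csv")
    write_table(
        [{"unit_id": u.unit_id, "time_s": t} for u in units for t in u.spike_times_s],
        spikes_path, columns=["unit_id", "time_s"],
    )
    write_table(
        [
            {"unit_id": u.unit_id, "sample_idx": i, "mV": v, "depth_um": u.depth_um,
             "cls": u.cls or "", "waveform_fs": u.waveform_fs}
            for u in units for i, v in enumerate(u.waveform_mv)
        ],
        waveforms_path,
        columns=["unit_id", "sample_idx", "mV", "depth_um", "cls", "waveform_fs"],
    )


def read_units(spikes_path: str | Path,
               waveforms_path: str | Path | None = None) -> list[SortedUnit]:
    spikes_path = Path(spikes_path)
    waveforms_path = Path(waveforms_path) if waveforms_path else spikes_path.with_name("waveforms.csv")
    st = read_table(spikes_path)
    wt = read_table(waveforms_path)
    units = []
    for uid, wgrp in wt.groupby("unit_id", sort=True):
        wgrp = wgrp.sort_values("sample_idx")
        spikes = np.sort(st.loc[st["unit_id"] == uid, "time_s"].to_numpy(dtype=float))
        cls = str(wgrp["cls"].iloc[0]) if "cls" in wgrp and str(wgrp["cls"].iloc[0]) in ("RS", "FS") else None
        units.append(SortedUnit(
            str(uid), spikes, wgrp["mV"].to_numpy(dtype=float),
            depth_um=float(wgrp["depth_um"].iloc[0]) if "depth_um" in wgrp else 0.0,
            cls=cls,
            waveform_fs=float(wgrp["waveform_fs"].iloc[0]) if "waveform_fs" in wgrp else 25_000.0,
        ))
    return units


def write_roi_traces(traces: RoiTraceSet, path: str | Path) -> None:
    recs = [
        {"roi_id": traces.roi_ids[r], "frame": f, "F": traces.F[r, f],
         "F_neuropil": traces.F_neuropil[r, f]}
        for r in range(traces.n_rois) for f in range(traces.F.shape[1])
    ]
    write_table(recs, path, columns=["roi_id", "frame", "F", "F_neuropil"])


def read_roi_traces(path: str | Path, frame_rate: float,
                    schedule: StimulusSchedule) -> RoiTraceSet:
    t = read_table(path)
    ids = list(dict.fromkeys(t["roi_id"]))
    F = np.stack([t.loc[t["roi_id"] == i].sort_values("frame")["F"].to_numpy() for i in ids])
    Fnp = np.stack([t.loc[t["roi_id"] == i].sort_values("frame")["F_neuropil"].to_numpy() for i in ids])
    return RoiTraceSet(F, Fnp, frame_rate, schedule, roi_ids=[str(i) for i in ids])
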