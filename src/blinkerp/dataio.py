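"""On-disk formats and in-memory containers for recordings and event tables.

A recording bundle is a directory with three files:

``data.f32``
    little-endian float32 binary, channels x samples, row-major, in microvolts
``meta.json``
    ``{"sampling_rate_hz", "channel_names", "subject_id", "run_id",
    "units": "uV", "n_channels", "n_samples"}``
``events.tsv``
    BIDS-events-style table: ``onset`` (seconds), ``duration`` (seconds),
    ``event_type``, ``trial_index``, ``run_id``

Onsets are stored in seconds on disk and milliseconds in memory; the
conversion is an exact factor of 1000. Time is 0-based from recording start.
All analysis windows are half-open ``[start, end)`` in ms, except the
blink-assignment window ``(0, 1500]`` which is exclusive on the left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_TYPES = ("standard", "target", "response", "blink")
EVENT_COLUMNS = ("onset_ms", "duration_ms", "event_type", "trial_index",
                 "run_id")


class FormatError(ValueError):
    """Raised when an on-disk bundle or table violates its contract."""


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts."""

    data: np.ndarray  # channels x samples, float
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    subject_id: str = "unknown"
    run_id: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise FormatError("data must be channels x samples")
        if self.data.shape[1] < 1:
            raise FormatError("recording must contain at least one sample")
        if self.data.shape[0] != len(self.channel_names):
            raise FormatError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel names must be unique")
        if not np.isfinite(self.data).all():
            raise FormatError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate_hz * 1000.0

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz * 1000.0


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table against its invariants; returns the table.

    Onsets must be non-decreasing within each run, event types known, and
    every response/blink row must carry the ``trial_index`` of its anchoring
    stimulus (or -1 if unassigned).
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table lacks columns {missing}")
    bad = set(events["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise FormatError(f"unknown event_type values: {sorted(bad)}")
    if not np.isfinite(events["onset_ms"].to_numpy(float)).all():
        raise FormatError("non-finite onset_ms")
    for run_id, grp in events.groupby("run_id", sort=False):
        onsets = grp["onset_ms"].to_numpy(float)
        if np.any(np.diff(onsets) < 0):
            raise FormatError(f"onsets not non-decreasing in run {run_id!r}")
    return events


def stimulus_events(events: pd.DataFrame) -> pd.DataFrame:
    return events[events["event_type"].isin(("standard", "target"))]


def write_recording(recording: Recording, events: pd.DataFrame, path) -> Path:
    """Write a recording bundle; returns the bundle directory."""
    validate_events(events)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data32 = np.ascontiguousarray(recording.data, dtype="<f4")
    data32.tofile(path / "data.f32")
    meta = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_names": list(recording.channel_names),
        "subject_id": recording.subject_id,
        "run_id": recording.run_id,
        "units": "uV",
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    out = events.loc[:, list(EVENT_COLUMNS)].copy()
    out.insert(0, "onset", out.pop("onset_ms") / 1000.0)
    out.insert(1, "duration", out.pop("duration_ms") / 1000.0)
    write_table(out, path / "events.tsv")
    return path


def read_recording(path) -> tuple[Recording, pd.DataFrame]:
    """Read a bundle written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("sampling_rate_hz", "channel_names", "n_channels",
                "n_samples"):
        if key not in meta:
            raise FormatError(f"sidecar lacks field {key!r}")
    raw = np.fromfile(path / "data.f32", dtype="<f4")
    expected = meta["n_channels"] * meta["n_samples"]
    if raw.size != expected:
        raise FormatError(
            f"data.f32 holds {raw.size} samples, sidecar announces "
            f"{expected} (n_channels x n_samples)")
    if len(meta["channel_names"]) != meta["n_channels"]:
        raise FormatError("sidecar n_channels disagrees with channel_names")
    rec = Recording(
        data=raw.reshape(meta["n_channels"], meta["n_samples"]),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channel_names=tuple(meta["channel_names"]),
        subject_id=str(meta.get("subject_id", "unknown")),
        run_id=str(meta.get("run_id", "unknown")),
    )
    ev = pd.read_csv(path / "events.tsv", sep="\t",
                     dtype={"run_id": str, "event_type": str})
    for col in ("onset", "duration"):
        if col not in ev.columns:
            raise FormatError(f"events.tsv lacks column {col!r}")
    ev["onset_ms"] = ev.pop("onset") * 1000.0
    ev["duration_ms"] = ev.pop("duration") * 1000.0
    ev = ev.loc[:, list(EVENT_COLUMNS)]
    validate_events(ev)
    return rec, ev


def write_table(table: pd.DataFrame, path) -> Path:
    """Write a TSV with stable column order and 6-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
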