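"""Blink peak extraction, first-blink assignment, event-related blinks.

Blink peaks (T0, the apex of the eyelid-closure deflection in the blink
component's time course) are detected as local maxima above a robust
threshold (median + 4 normal-consistent MAD, i.e. 4 robust sigma)
separated by at least a 200 ms refractory window;
the trace polarity is first normalized so blink deflections are positive
(sign chosen to make the skewness positive).

Each stimulus is then assigned at most the FIRST detected blink whose peak
falls in the (0, 1500] ms window after stimulus onset; later in-window
blinks are excluded, and a blink is consumed by at most one stimulus (the
earlier one in the pathological case of overlapping windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .dataio import stimulus_events

#: first-blink assignment window after stimulus onset, exclusive left,
#: inclusive right (ms)
ASSIGNMENT_WINDOW_MS = (0.0, 1500.0)


@dataclass
class BlinkTimes:
    """Sorted blink peak instants (ms from recording start) for one run."""

    subject_id: str
    run_id: str
    t0_ms: np.ndarray
    refractory_ms: float = 200.0

    def __post_init__(self):
        self.t0_ms = np.asarray(self.t0_ms, dtype=float)
        if np.any(np.diff(self.t0_ms) <= 0):
            raise ValueError("blink times must be strictly increasing")
        if self.t0_ms.size > 1 and \
                np.min(np.diff(self.t0_ms)) < self.refractory_ms - 1e-9:
            raise ValueError("blink peaks closer than the refractory window")

    def __len__(self):
        return self.t0_ms.size


def detect_blink_peaks(blink_source: np.ndarray, sampling_rate_hz: float,
                       subject_id: str = "unknown", run_id: str = "unknown",
                       threshold_mads: float = 4.0,
                       refractory_ms: float = 200.0) -> BlinkTimes:
    """Detect blink peak times on a blink-component time course.

    Local maxima above ``median + threshold_mads * MAD`` with a minimum
    separation of ``refractory_ms`` (the larger peak wins within the
    window). A flat trace yields no peaks, with a warning.
    """
    x = np.asarray(blink_source, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        warnings.warn("flat blink trace: no peaks detected", stacklevel=2)
        return BlinkTimes(subject_id, run_id, np.empty(0),
                          refractory_ms=refractory_ms)
    if stats.skew(x) < 0:  # polarity so blink deflections are positive
        x = -x
    mad = stats.median_abs_deviation(x, scale="normal")
    if mad == 0:
        mad = x.std() or 1.0
    threshold = np.median(x) + threshold_mads * mad
    distance = max(1, int(round(refractory_ms / 1000.0 * sampling_rate_hz)))
    peaks, _ = find_peaks(x, height=threshold, distance=distance)
    t0 = peaks / sampling_rate_hz * 1000.0
    return BlinkTimes(subject_id, run_id, t0, refractory_ms=refractory_ms)


def assign_first_blinks(blinks: BlinkTimes, events: pd.DataFrame,
                        window_ms: tuple[float, float] = ASSIGNMENT_WINDOW_MS
                        ) -> pd.DataFrame:
    """First-blink-per-stimulus assignment over one run's event table.

    Returns one row per stimulus with columns ``trial_index``,
    ``stimulus_type``, ``stimulus_onset_ms``, ``blink_t0_ms`` (NaN when no
    blink assigned), ``latency_ms`` (from stimulus onset) and
    ``latency_from_response_ms`` (responded targets only). The window is
    exclusive-left, inclusive-right. Each detected blink is assigned to at
    most one stimulus; adding blinks outside all windows never changes the
    assignment.
    """
    lo, hi = window_ms
    stims = stimulus_events(events)
    if "run_id" in events.columns and len(stims):
        run_ids = set(stims["run_id"])
        if blinks.run_id in run_ids:
            stims = stims[stims["run_id"] == blinks.run_id]
    responses = events[events["event_type"] == "response"]
    rt_by_trial = dict(zip(responses["trial_index"], responses["onset_ms"]))
    t0 = blinks.t0_ms
    used = np.zeros(t0.size, dtype=bool)
    rows = []
    for _, stim in stims.sort_values("onset_ms").iterrows():
        onset = float(stim["onset_ms"])
        in_window = (t0 > onset + lo) & (t0 <= onset + hi) & ~used
        idx = np.flatnonzero(in_window)
        row = {"trial_index": stim["trial_index"],
               "stimulus_type": stim["event_type"],
               "stimulus_onset_ms": onset,
               "blink_t0_ms": np.nan, "latency_ms": np.nan,
               "latency_from_response_ms": np.nan}
        if idx.size:
            first = idx[0]  # earliest in-window blink; later ones excluded
            used[first] = True
            row["blink_t0_ms"] = t0[first]
            row["latency_ms"] = t0[first] - onset
            resp = rt_by_trial.get(stim["trial_index"])
            if resp is not None and stim["event_type"] == "target":
                row["latency_from_response_ms"] = t0[first] - resp
        rows.append(row)
    return pd.DataFrame(rows, columns=["trial_index", "stimulus_type",
                                       "stimulus_onset_ms", "blink_t0_ms",
                                       "latency_ms",
                                       "latency_from_response_ms"])


def blink_summary(assignments: pd.DataFrame, blinks: BlinkTimes,
                  duration_min: float, subject_id: str = "") -> dict:
    """Per-subject blink behaviour summary (pooled over runs upstream)."""
    std = assignments[assignments["stimulus_type"] == "standard"]
    trg = assignments[assignments["stimulus_type"] == "target"]
    return {
        "subject_id": subject_id or blinks.subject_id,
        "n_blinks": int(len(blinks)),
        "blink_rate_per_min": len(blinks) / duration_min
        if duration_min else np.nan,
        "pct_standard_epochs_with_blink":
            100.0 * std["blink_t0_ms"].notna().mean() if len(std) else np.nan,
        "pct_target_epochs_with_blink":
            100.0 * trg["blink_t0_ms"].notna().mean() if len(trg) else np.nan,
        "mean_latency_standard_ms": float(std["latency_ms"].mean()),
        "mean_latency_target_ms": float(trg["latency_ms"].mean()),
        "mean_latency_from_response_ms":
            float(trg["latency_from_response_ms"].mean()),
    }


def compute_erb(blink_signal, anchors_ms, sampling_rate_hz: float,
                window_ms: tuple[float, float] = (-500.0, 1500.0),
                mode: str = "trace") -> tuple[np.ndarray, np.ndarray]:
    """Event-related blink waveform around a set of anchor events.

    ``mode="trace"`` averages the max-normalized blink-component time course;
    ``mode="indicator"`` averages a binary blink-occurrence train (requires
    ``blink_signal`` to be a :class:`BlinkTimes`). Returns
    ``(time_axis_ms, waveform)``. Anchors whose window exceeds the signal
    are dropped.
    """
    anchors = np.asarray(anchors_ms, dtype=float)
    if anchors.size == 0:
        raise ValueError("anchor list must be non-empty")
    fs = sampling_rate_hz
    if mode == "indicator":
        if not isinstance(blink_signal, BlinkTimes):
            raise TypeError("indicator mode requires BlinkTimes")
        end = max(anchors.max() + window_ms[1],
                  blink_signal.t0_ms.max() if len(blink_signal) else 0) + 1000
        trace = np.zeros(int(np.ceil(end / 1000.0 * fs)))
        idx = np.round(blink_signal.t0_ms / 1000.0 * fs).astype(int)
        trace[idx[idx < trace.size]] = 1.0
    elif mode == "trace":
        trace = np.asarray(blink_signal, dtype=float)
        peak = np.abs(trace).max()
        if peak > 0:
            trace = (trace if stats.skew(trace) >= 0 else -trace) / peak
    else:
        raise ValueError("mode must be 'trace' or 'indicator'")
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    segments = []
    for a in anchors:
        c = int(round(a / 1000.0 * fs))
        if c + lo >= 0 and c + hi <= trace.size:
            segments.append(trace[c + lo:c + hi])
    if not segments:
        raise ValueError("no anchor window fits inside the signal")
    waveform = np.mean(segments, axis=0)
    times = (np.arange(lo, hi) / fs) * 1000.0
    return times, waveform
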