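"""Parameter-recovery measurements on synthetic cohorts.

These helpers run the end-to-end blink pipeline (simulate -> ICA -> blink
component -> peak detection -> first-blink assignment) subject by subject
and pool the results, so that the generator's behavioural statistics (blink
proportions and latencies, hit rate, response times) can be recovered by
measurement rather than read off the configuration. They are used both by
the test suite and by the reproduction script.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .blinks import assign_first_blinks, detect_blink_peaks
from .config import BehaviourConfig, NoiseConfig, ProtocolConfig
from .decompose import blink_component, classify_components, run_ica
from .pipeline import _concatenate_runs
from .synthio import (build_stimulus_schedule, default_source_model,
                      derive_seeds, sample_behaviour, simulate_subject)

logger = logging.getLogger(__name__)


def subject_blink_measurement(seed: int, subject_id: str,
                              protocol: ProtocolConfig | None = None,
                              behaviour: BehaviourConfig | None = None,
                              noise: NoiseConfig | None = None,
                              sources=None,
                              ica_fit_samples: int = 20000) -> pd.DataFrame:
    """End-to-end blink measurement of one simulated subject.

    Returns the first-blink assignment table (one row per stimulus) with a
    ``subject_id`` column, measured from the rendered recording via ICA and
    peak detection — not from the generator's truth table.
    """
    protocol = protocol or ProtocolConfig()
    subject = simulate_subject(seed, subject_id=subject_id,
                               protocol=protocol, behaviour=behaviour,
                               sources=sources, noise=noise)
    recording, events = _concatenate_runs(subject)
    dec = run_ica(recording, rng_seed=seed,
                  max_fit_samples=ica_fit_samples)
    classify_components(dec)
    b = blink_component(dec)
    if b is None:
        logger.warning("subject %s: no blink component", subject_id)
        frame = pd.DataFrame(columns=["trial_index", "stimulus_type",
                                      "stimulus_onset_ms", "blink_t0_ms",
                                      "latency_ms",
                                      "latency_from_response_ms"])
    else:
        times = detect_blink_peaks(dec.sources[b],
                                   recording.sampling_rate_hz,
                                   subject_id=subject_id)
        frame = assign_first_blinks(times, events)
    return frame.assign(subject_id=subject_id)


def pooled_blink_assignments(master_seed: int,
                             behaviour: BehaviourConfig | None = None,
                             protocol: ProtocolConfig | None = None,
                             n_subjects: int = 17,
                             min_standard_blinks: int = 0,
                             min_target_blinks: int = 0,
                             max_subjects: int = 100) -> pd.DataFrame:
    """Pool per-subject blink measurements across a seeded cohort.

    At least ``n_subjects`` subjects are simulated; more are added (up to
    ``max_subjects``) until the pooled assigned-blink counts reach the
    requested minima, so latency means can be estimated at a prescribed
    pooling size.
    """
    behaviour = behaviour or BehaviourConfig()
    protocol = protocol or ProtocolConfig()
    sources = default_source_model(protocol)
    seeds = derive_seeds(master_seed, max_subjects, "recovery")
    frames = []
    n_std = n_trg = 0
    for i in range(max_subjects):
        if i >= n_subjects and n_std >= min_standard_blinks \
                and n_trg >= min_target_blinks:
            break
        frame = subject_blink_measurement(
            seeds[i], f"sub-{i + 1:03d}", protocol=protocol,
            behaviour=behaviour, sources=sources)
        frames.append(frame)
        assigned = frame[frame["blink_t0_ms"].notna()]
        n_std += int((assigned["stimulus_type"] == "standard").sum())
        n_trg += int((assigned["stimulus_type"] == "target").sum())
    return pd.concat(frames, ignore_index=True)


def blink_statistics(assignments: pd.DataFrame) -> dict:
    """Pooled blink-epoch proportions and latency means from assignments."""
    std = assignments[assignments["stimulus_type"] == "standard"]
    trg = assignments[assignments["stimulus_type"] == "target"]
    resp = trg[trg["latency_from_response_ms"].notna()]
    return {
        "n_standard_trials": int(len(std)),
        "n_target_trials": int(len(trg)),
        "n_standard_blinks": int(std["blink_t0_ms"].notna().sum()),
        "n_target_blinks": int(trg["blink_t0_ms"].notna().sum()),
        "pct_standard_with_blink":
            100.0 * float(std["blink_t0_ms"].notna().mean()),
        "pct_target_with_blink":
            100.0 * float(trg["blink_t0_ms"].notna().mean()),
        "mean_latency_standard_ms": float(std["latency_ms"].mean()),
        "mean_latency_target_ms": float(trg["latency_ms"].mean()),
        "mean_latency_from_response_ms":
            float(resp["latency_from_response_ms"].mean()),
        "n_response_anchored_blinks": int(len(resp)),
    }


def behaviour_statistics(master_seed: int, min_targets: int = 2000,
                         behaviour: BehaviourConfig | None = None,
                         protocol: ProtocolConfig | None = None) -> dict:
    """Simulated hit rate (%) and mean RT (ms) over >= ``min_targets``.

    Works at the event-table level (no rendering): target trials are
    accumulated over seeded simulated sessions until the minimum count is
    reached, then the percentage of responded targets and the mean response
    latency are measured from the event tables.
    """
    behaviour = behaviour or BehaviourConfig()
    protocol = protocol or ProtocolConfig()
    per_session = protocol.n_runs * protocol.n_targets_per_run
    n_sessions = int(np.ceil(min_targets / max(per_session, 1)))
    seeds = derive_seeds(master_seed, 2 * n_sessions, "behaviour")
    n_targets = n_hits = 0
    rts = []
    for i in range(n_sessions):
        schedule = build_stimulus_schedule(protocol, seeds[2 * i])
        events = sample_behaviour(schedule, behaviour, seeds[2 * i + 1])
        stims = events[events["event_type"] == "target"]
        resp = events[events["event_type"] == "response"]
        onset = dict(zip(stims["trial_index"], stims["onset_ms"]))
        n_targets += len(stims)
        n_hits += len(resp)
        rts.extend(r["onset_ms"] - onset[r["trial_index"]]
                   for _, r in resp.iterrows())
    return {"n_targets": n_targets, "n_hits": n_hits,
            "hit_rate_pct": 100.0 * n_hits / n_targets,
            "mean_rt_ms": float(np.mean(rts))}
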