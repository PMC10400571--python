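"""End-to-end orchestration: simulate -> decompose -> cluster -> dipole-fit
-> blink extraction -> ERP statistics, reproducible from one master seed.

Each subject's runs are simulated and (by default) concatenated for a single
full-rank ICA; with ``ica_per_run`` each run is decomposed separately and
every run's maps are offered to the group clustering as candidates. Blink
components are identified by the heuristic classifier, blink peaks detected
on their time courses, and first blinks assigned to stimuli. Subject maps
are clustered at the group level, cluster centroids are described by
equivalent dipoles and labelled by nearest grey matter, and the scalp signal
is reconstructed from the components of the ROI-labelled clusters
("precuneus" by default). ERPs at Pz are then extracted, averaged, and
compared with FDR-corrected pointwise paired t-tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blinks import (assign_first_blinks, blink_summary, detect_blink_peaks)
from .config import PipelineConfig, config_to_dict
from .dataio import Recording, write_table
from .decompose import blink_component, classify_components, run_ica, backproject
from .dipolefit import HeadModel, fit_dipole
from .erpstats import (EPOCH_TYPES, ComparisonResult, average_erp,
                       extract_epochs, run_comparisons)
from .groupcluster import ComponentMap, cluster_maps, select_roi_clusters
from .synthio import default_source_model, derive_seeds, simulate_subject

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, original: Exception):
        super().__init__(f"stage {stage!r} failed for subject "
                         f"{subject_id!r}: {original}")
        self.stage = stage
        self.subject_id = subject_id


@dataclass
class SubjectResult:
    subject_id: str
    recording: Recording  # concatenated runs
    events: pd.DataFrame  # onsets on the concatenated time axis
    decompositions: list  # one (concatenated) or one per run
    blink_index: tuple | None  # (dataset, component)
    assignments: pd.DataFrame = None
    blink_times: object = None
    epoch_counts: dict = field(default_factory=dict)


@dataclass
class RunReport:
    config: dict
    seeds: dict
    subjects: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list)
    dipoles: list = field(default_factory=list)
    roi_selection: dict = field(default_factory=dict)
    anchors: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    software: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)
        return json.dumps(dataclasses.asdict(self), default=default,
                          indent=1)


def _concatenate_runs(subject) -> tuple[Recording, pd.DataFrame]:
    """Join runs on a single time axis; event onsets become global."""
    offsets_ms = []
    total = 0
    fs = subject.recordings[0].sampling_rate_hz
    for rec in subject.recordings:
        offsets_ms.append(total / fs * 1000.0)
        total += rec.n_samples
    data = np.concatenate([r.data for r in subject.recordings], axis=1)
    events = subject.events.copy()
    run_ids = [r.run_id for r in subject.recordings]
    offset_by_run = dict(zip(run_ids, offsets_ms))
    events["onset_ms"] = [o + offset_by_run[r] for o, r in
                          zip(events["onset_ms"], events["run_id"])]
    rec = Recording(data=data, sampling_rate_hz=fs,
                    channel_names=subject.recordings[0].channel_names,
                    subject_id=subject.subject_id, run_id="concat")
    return rec, events


def process_subject(subject, config: PipelineConfig,
                    ica_seed: int) -> SubjectResult:
    """Decompose one simulated subject and extract its blink behaviour."""
    sid = subject.subject_id
    recording, events = _concatenate_runs(subject)
    try:
        if config.ica_per_run:
            datasets = [(rec, subject.events[
                subject.events["run_id"] == rec.run_id])
                for rec in subject.recordings]
        else:
            datasets = [(recording, events)]
        decs = []
        for k, (rec, _) in enumerate(datasets):
            dec = run_ica(rec, rng_seed=(ica_seed + k) % (2 ** 31),
                          max_fit_samples=config.ica_fit_samples)
            classify_components(dec)
            decs.append(dec)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("decompose", sid, err) from err
    try:
        blink_idx = None
        assignments = []
        blink_times = None
        for k, (dec, (rec, ev)) in enumerate(zip(decs, datasets)):
            b = blink_component(dec)
            if b is None:
                continue
            if blink_idx is None or (
                    dec.features[b]["frontopolar_concentration"]
                    > decs[blink_idx[0]].features[blink_idx[1]]
                    ["frontopolar_concentration"]):
                blink_idx = (k, b)
        if blink_idx is not None:
            k, b = blink_idx
            dec, (rec, ev) = decs[k], datasets[k]
            blink_times = detect_blink_peaks(
                dec.sources[b], rec.sampling_rate_hz, subject_id=sid,
                run_id=rec.run_id)
            assignments = assign_first_blinks(blink_times, ev)
        else:
            logger.warning("subject %s: no blink component found", sid)
            assignments = pd.DataFrame(
                columns=["trial_index", "stimulus_type",
                         "stimulus_onset_ms", "blink_t0_ms", "latency_ms",
                         "latency_from_response_ms"])
    except Exception as err:  # noqa: BLE001
        raise PipelineError("blinks", sid, err) from err
    return SubjectResult(subject_id=sid, recording=recording, events=events,
                         decompositions=decs, blink_index=blink_idx,
                         assignments=assignments, blink_times=blink_times)


def load_cohort(in_dir) -> list:
    """Load a cohort written by ``blinkerp simulate`` (per-run bundles)."""
    from .dataio import read_recording
    from .synthio import SubjectData

    in_dir = Path(in_dir)
    subjects = []
    for sub_dir in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        run_dirs = sorted(p for p in sub_dir.iterdir()
                          if p.is_dir() and (p / "meta.json").exists())
        if not run_dirs:
            continue
        recordings, frames = [], []
        for run_dir in run_dirs:
            rec, ev = read_recording(run_dir)
            recordings.append(rec)
            frames.append(ev)
        subjects.append(SubjectData(
            subject_id=sub_dir.name, recordings=recordings,
            events=pd.concat(frames, ignore_index=True), truths=[]))
    if not subjects:
        raise FileNotFoundError(f"no recording bundles under {in_dir}")
    return subjects


def run_pipeline(config: PipelineConfig, out_dir=None,
                 subjects=None) -> RunReport:
    """Run the full pipeline; returns the run report (artifacts optional).

    Deterministic given ``config.master_seed``: subject simulations, ICA and
    clustering all derive their seeds from it. With ``subjects`` given
    (e.g. from :func:`load_cohort`), the simulation stage is skipped and the
    provided cohort is analysed instead.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    headmodel = HeadModel(channel_names=config.protocol.channel_names)
    n = config.n_subjects if subjects is None else len(subjects)
    subj_seeds = derive_seeds(config.master_seed, n, "simulate")
    ica_seeds = derive_seeds(config.master_seed, n, "ica")
    cluster_seed = derive_seeds(config.master_seed, 1, "cluster")[0]

    report = RunReport(
        config=config_to_dict(config),
        seeds={"master": config.master_seed, "subjects": subj_seeds,
               "ica": ica_seeds, "cluster": cluster_seed},
        software={"package": "blinkerp", "version": __version__,
                  "ica_algorithm": "fastica"})

    results: list[SubjectResult] = []
    if subjects is None:
        sources = default_source_model(config.protocol, headmodel)
        subjects = []
        for i in range(n):
            sid = f"sub-{i + 1:02d}"
            try:
                subjects.append(simulate_subject(
                    subj_seeds[i], subject_id=sid, protocol=config.protocol,
                    behaviour=config.behaviour, sources=sources,
                    noise=config.noise))
            except Exception as err:  # noqa: BLE001
                raise PipelineError("simulate", sid, err) from err
    for subject, ica_seed in zip(subjects, ica_seeds):
        results.append(process_subject(subject, config, ica_seed))
        logger.info("subject %s processed", subject.subject_id)

    # group clustering over every component map of every subject
    maps = []
    for res in results:
        for k, dec in enumerate(res.decompositions):
            for c in range(dec.n_components):
                col = dec.mixing[:, c]
                if np.linalg.norm(col) == 0:
                    continue
                maps.append(ComponentMap(res.subject_id, (k, c), col))
    try:
        cluster_result = cluster_maps(maps, alpha=config.alpha,
                                      rng_seed=cluster_seed)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("cluster", "group", err) from err

    try:
        fits = [fit_dipole(cl.centroid, headmodel)
                for cl in cluster_result.clusters]
        selection = select_roi_clusters(
            cluster_result, fits, config.roi_label,
            known_labels=set(headmodel.grey_labels))
    except Exception as err:  # noqa: BLE001
        raise PipelineError("dipolefit", "group", err) from err

    report.clusters = [
        {"cluster": i, "size": len(cl.members), "cluster_p": cl.cluster_p,
         "mean_similarity": cl.mean_similarity,
         "members": [list(map(str, m)) for m in cl.members]}
        for i, cl in enumerate(cluster_result.clusters)]
    report.dipoles = [
        {"cluster": i, "position_mm": f.position_mm.tolist(),
         "residual_variance": f.residual_variance, "label": f.label}
        for i, f in enumerate(fits)]
    report.roi_selection = {s: [list(c) for c in comps]
                            for s, comps in selection.items()}

    # per-subject ROI reconstruction and epoch extraction
    per_type: dict[str, dict] = {t: {} for t in EPOCH_TYPES}
    blink_rows = []
    all_assignments = []
    for res in results:
        sid = res.subject_id
        counts = {"n_components": sum(d.n_components
                                      for d in res.decompositions),
                  "labels": {lab: sum(d.labels.count(lab)
                                      for d in res.decompositions)
                             for lab in ("brain", "blink", "other")},
                  "n_blinks": int(len(res.blink_times))
                  if res.blink_times is not None else 0}
        comps = selection.get(sid, [])
        if res.blink_times is not None and len(res.assignments):
            all_assignments.append(res.assignments.assign(subject_id=sid))
            blink_rows.append(blink_summary(
                res.assignments, res.blink_times,
                res.recording.n_samples / res.recording.sampling_rate_hz
                / 60.0, subject_id=sid))
        if comps:
            try:
                by_dataset: dict[int, list] = {}
                for (k, c) in comps:
                    by_dataset.setdefault(k, []).append(c)
                if config.ica_per_run and len(res.decompositions) > 1:
                    # reconstruct each run then re-concatenate
                    parts = []
                    for k, dec in enumerate(res.decompositions):
                        cs = by_dataset.get(k)
                        part = backproject(dec, cs).data if cs else \
                            np.zeros((dec.mixing.shape[0],
                                      dec.sources.shape[1]))
                        parts.append(part)
                    roi_data = np.concatenate(parts, axis=1)
                else:
                    k = next(iter(by_dataset))
                    roi_data = backproject(res.decompositions[k],
                                           by_dataset[k]).data
                roi_rec = Recording(roi_data,
                                    res.recording.sampling_rate_hz,
                                    res.recording.channel_names,
                                    subject_id=sid, run_id="roi")
                for epoch_type in EPOCH_TYPES:
                    locking, cls = epoch_type.split("-")
                    eset = extract_epochs(
                        roi_rec, res.events, locking, cls,
                        assignments=res.assignments,
                        channel=config.analysis_channel)
                    per_type[epoch_type][sid] = eset
                    counts[epoch_type] = eset.n_epochs
            except Exception as err:  # noqa: BLE001
                raise PipelineError("epochs", sid, err) from err
        report.subjects[sid] = counts

    assignments = pd.concat(all_assignments, ignore_index=True) \
        if all_assignments else pd.DataFrame()
    responses = []
    for res in results:
        resp = res.events[res.events["event_type"] == "response"]
        stims = res.events[res.events["event_type"] == "target"]
        onset = dict(zip(stims["trial_index"], stims["onset_ms"]))
        responses.extend(r["onset_ms"] - onset[r["trial_index"]]
                         for _, r in resp.iterrows()
                         if r["trial_index"] in onset)
    mean_rt = float(np.mean(responses)) if responses else np.nan
    latency = {}
    for cls in ("standard", "target"):
        sel = assignments[assignments.get("stimulus_type", pd.Series(
            dtype=object)) == cls] if len(assignments) else []
        latency[cls] = float(sel["latency_ms"].mean()) if len(sel) else np.nan
    report.anchors = {"mean_rt_ms": mean_rt,
                      "mean_blink_latency_ms": latency}

    comparisons: list[ComparisonResult] = []
    erps = {}
    complete = all(len(per_type[t]) >= 3 for t in EPOCH_TYPES)
    if complete:
        erps = {t: average_erp(per_type[t], t) for t in EPOCH_TYPES}
        try:
            comparisons = run_comparisons(
                erps, mean_rt, latency, alpha=config.alpha,
                align=config.align_before_test)
        except Exception as err:  # noqa: BLE001
            raise PipelineError("compare", "group", err) from err
        report.comparisons = [
            {"comparison": c.comparison, "pair": list(c.pair),
             "rule": c.rule, "shift_ms": c.shift_ms,
             "n_significant": int(c.stat.sig_mask.sum()),
             "woi_fraction_significant": c.woi_fractions}
            for c in comparisons]
    else:
        logger.warning("fewer than 3 subjects with ROI epochs; "
                       "comparisons skipped")

    if out is not None:
        _write_artifacts(out, report, erps, comparisons, blink_rows,
                         assignments)
    report._erps = erps  # in-memory conveniences, not serialized
    report._comparisons = comparisons
    report._assignments = assignments
    report._results = results
    return report


def _write_artifacts(out: Path, report: RunReport, erps, comparisons,
                     blink_rows, assignments):
    (out / "run_report.json").write_text(report.to_json())
    if blink_rows:
        write_table(pd.DataFrame(blink_rows), out / "blink_summary.tsv")
    if len(assignments):
        write_table(assignments, out / "blink_assignments.tsv")
    for name, erp in erps.items():
        frame = pd.DataFrame(erp.subject_means.T,
                             columns=erp.subject_ids)
        frame.insert(0, "time_ms", erp.time_axis_ms)
        frame["grand_average"] = erp.grand_average
        write_table(frame, out / f"erp_{name}.tsv")
    for comp in comparisons:
        stat = comp.stat
        frame = pd.DataFrame({
            "time_ms": stat.time_axis_ms, "t": stat.t, "p": stat.p,
            "q": stat.q, "significant": stat.sig_mask.astype(int),
            "tested": stat.tested_region.astype(int)})
        write_table(frame, out / f"stats_comparison{comp.comparison}.tsv")
    if comparisons:
        rows = []
        for comp in comparisons:
            for woi, frac in comp.woi_fractions.items():
                rows.append({"comparison": comp.comparison,
                             "pair": "-vs-".join(comp.pair), "woi": woi,
                             "fraction_significant": frac})
        write_table(pd.DataFrame(rows), out / "woi_summary.tsv")
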