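"""Epoch extraction, grand averages, alignment, FDR-corrected comparisons.

Five epoch types are analysed on a single channel (Pz by default, taken
from the ROI-reconstructed recording): stimulus-locked standards and
targets (SL-STND, SL-TRGT, window [-500, +1500) ms around stimulus onset),
response-locked targets (RL-TRGT, same window around the button press), and
blink-locked epochs (BL-STND, BL-TRGT, [-1500, +500) ms around the blink
peak, using only first-assigned blinks). Every epoch — whatever its locking
— is baseline-corrected by subtracting the mean of the 500 ms preceding its
trial's STIMULUS onset.

Six planned comparisons are evaluated pointwise with paired t-tests over
the post-stimulus (comparisons 1-5) or post-blink (comparison 6) region and
corrected with Benjamini-Hochberg FDR. When the two conditions have
different locking, the second waveform is shifted onto the first one's axis
by the cohort's measured mean response time or mean blink latency and the
test is restricted to the overlap. Significance is summarised over fixed
windows of interest (WOIs) derived from mean event latencies plus the
expected component latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataio import Recording

logger = logging.getLogger(__name__)

LOCKINGS = ("SL", "RL", "BL")
STIM_CLASSES = {"STND": "standard", "TRGT": "target"}
EPOCH_TYPES = ("SL-STND", "SL-TRGT", "RL-TRGT", "BL-STND", "BL-TRGT")

#: epoch windows, ms, half-open
EPOCH_WINDOWS = {"SL": (-500.0, 1500.0), "RL": (-500.0, 1500.0),
                 "BL": (-1500.0, 500.0)}
BASELINE_MS = 500.0  # baseline: the 500 ms preceding the stimulus


@dataclass(frozen=True)
class WOI:
    """A window of interest: fixed latency interval on an event axis."""

    name: str
    start_ms: float
    end_ms: float
    reference: str  # "stimulus" | "blink"
    derivation: str = ""


#: Fixed WOI catalogue. The composite windows add the mean blink (or
#: response + blink) latency to the ~300 ms blink-to-BRP latency.
WOI_CATALOGUE = {
    "yellow": WOI("yellow", 300.0, 500.0, "stimulus",
                  "expected P300 latency"),
    "orange": WOI("orange", 400.0, 600.0, "stimulus",
                  "expected response-locked P300 latency"),
    "purple": WOI("purple", 800.0, 1000.0, "stimulus",
                  "595 ms mean standard blink latency + 300 ms BRP"),
    "pink": WOI("pink", 1000.0, 1200.0, "stimulus",
                "779 ms mean target blink latency + 300 ms BRP"),
    "cyan": WOI("cyan", 1100.0, 1300.0, "stimulus",
                "397 ms RT + 511 ms blink-from-response + 300 ms BRP"),
    "bl_brp": WOI("bl_brp", 200.0, 400.0, "blink",
                  "expected BRP latency from the blink peak"),
}

#: comparison id -> (condition A, condition B, alignment rule, relevant WOIs)
COMPARISONS = {
    1: ("SL-STND", "SL-TRGT", "none", ("yellow", "purple", "pink")),
    2: ("SL-STND", "RL-TRGT", "shift_by_mean_rt",
        ("yellow", "orange", "purple", "cyan")),
    3: ("SL-TRGT", "RL-TRGT", "shift_by_mean_rt", ("orange", "cyan")),
    4: ("SL-STND", "BL-STND", "shift_by_mean_blink_latency:standard",
        ("purple",)),
    5: ("SL-TRGT", "BL-TRGT", "shift_by_mean_blink_latency:target",
        ("pink",)),
    6: ("BL-STND", "BL-TRGT", "none", ("bl_brp",)),
}


@dataclass
class EpochSet:
    """Baselined single-channel epochs of one locking/class combination."""

    epochs: np.ndarray  # trials x timepoints
    time_axis_ms: np.ndarray
    locking: str
    stimulus_class: str  # "STND" | "TRGT"
    trial_indices: np.ndarray
    channel: str = "Pz"
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def mean(self) -> np.ndarray:
        return self.epochs.mean(axis=0)


@dataclass
class ERP:
    """Per-subject mean waveforms and their unweighted grand average."""

    subject_ids: list
    subject_means: np.ndarray  # subjects x timepoints
    time_axis_ms: np.ndarray
    n_epochs: dict  # subject_id -> count
    epoch_type: str = ""

    @property
    def grand_average(self) -> np.ndarray:
        return self.subject_means.mean(axis=0)


@dataclass
class StatResult:
    """Pointwise paired-test result over a tested region."""

    time_axis_ms: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_mask: np.ndarray
    tested_region: np.ndarray  # boolean mask on time_axis_ms
    alpha: float


def extract_epochs(recording: Recording, events: pd.DataFrame, locking: str,
                   stimulus_class: str, assignments: pd.DataFrame = None,
                   channel: str = "Pz") -> EpochSet:
    """Extract baselined single-channel epochs from one run.

    ``assignments`` (from first-blink assignment) is required for BL
    epochs; RL epochs require response events. Epochs whose window or
    baseline extends past the recording edges are dropped (counted in
    ``n_dropped``); zero surviving epochs is an error.
    """
    if locking not in LOCKINGS:
        raise ValueError(f"locking must be one of {LOCKINGS}")
    if stimulus_class not in STIM_CLASSES:
        raise ValueError("stimulus_class must be 'STND' or 'TRGT'")
    event_type = STIM_CLASSES[stimulus_class]
    fs = recording.sampling_rate_hz
    trace = recording.channel(channel) if channel in recording.channel_names \
        else recording.data[0]
    stims = events[events["event_type"] == event_type]
    stim_onset = dict(zip(stims["trial_index"], stims["onset_ms"]))

    if locking == "SL":
        anchors = [(t, onset) for t, onset in
                   zip(stims["trial_index"], stims["onset_ms"])]
    elif locking == "RL":
        if stimulus_class != "TRGT":
            raise ValueError("RL epochs exist only for target stimuli")
        resp = events[events["event_type"] == "response"]
        anchors = [(t, onset) for t, onset in
                   zip(resp["trial_index"], resp["onset_ms"])
                   if t in stim_onset]
        if not anchors:
            raise ValueError("no response events for RL epochs")
    else:  # BL
        if assignments is None:
            raise ValueError("BL epochs require first-blink assignments")
        sel = assignments[(assignments["stimulus_type"] == event_type)
                          & assignments["blink_t0_ms"].notna()]
        anchors = list(zip(sel["trial_index"], sel["blink_t0_ms"]))

    lo_ms, hi_ms = EPOCH_WINDOWS[locking]
    lo = int(round(lo_ms / 1000.0 * fs))
    hi = int(round(hi_ms / 1000.0 * fs))
    base_len = int(round(BASELINE_MS / 1000.0 * fs))
    segs, trials, dropped = [], [], 0
    for trial, anchor_ms in anchors:
        c = int(round(anchor_ms / 1000.0 * fs))
        s0 = int(round(stim_onset[trial] / 1000.0 * fs))
        if c + lo < 0 or c + hi > trace.size or s0 - base_len < 0 \
                or s0 > trace.size:
            dropped += 1
            continue
        baseline = trace[s0 - base_len:s0].mean()
        segs.append(trace[c + lo:c + hi] - baseline)
        trials.append(trial)
    if dropped:
        logger.info("dropped %d %s-%s epochs at recording edges",
                    dropped, locking, stimulus_class)
    if not segs:
        raise ValueError(f"zero surviving {locking}-{stimulus_class} epochs")
    times = np.arange(lo, hi) / fs * 1000.0
    return EpochSet(epochs=np.stack(segs), time_axis_ms=times,
                    locking=locking, stimulus_class=stimulus_class,
                    trial_indices=np.asarray(trials), channel=channel,
                    n_dropped=dropped)


def concatenate_epochs(epochsets) -> EpochSet:
    """Pool epoch sets of the same kind (e.g. across runs)."""
    epochsets = [e for e in epochsets if e is not None]
    first = epochsets[0]
    return EpochSet(
        epochs=np.concatenate([e.epochs for e in epochsets]),
        time_axis_ms=first.time_axis_ms, locking=first.locking,
        stimulus_class=first.stimulus_class,
        trial_indices=np.concatenate([e.trial_indices for e in epochsets]),
        channel=first.channel,
        n_dropped=sum(e.n_dropped for e in epochsets))


def average_erp(per_subject: dict, epoch_type: str = "") -> ERP:
    """Subject means then unweighted grand mean.

    ``per_subject`` maps subject_id -> EpochSet (one epoch type).
    """
    if not per_subject:
        raise ValueError("need at least one subject")
    subject_ids = sorted(per_subject)
    means = np.stack([per_subject[s].mean() for s in subject_ids])
    first = per_subject[subject_ids[0]]
    return ERP(subject_ids=subject_ids, subject_means=means,
               time_axis_ms=first.time_axis_ms,
               n_epochs={s: per_subject[s].n_epochs for s in subject_ids},
               epoch_type=epoch_type)


def align_for_comparison(erp_a: ERP, erp_b: ERP, rule: str,
                         shift_ms: float = 0.0):
    """Map condition B onto condition A's time axis.

    ``rule`` is ``none`` (axes compared as-is) or one of the shift rules
    (``shift_by_mean_rt``, ``shift_by_mean_blink_latency``); the shift value
    itself is measured from the data by the caller and passed in. B's 0 ms
    lands at ``shift_ms`` on A's axis; B is linearly interpolated onto A's
    sample grid and both are restricted to the overlap.

    Returns ``(time_axis, a_means, b_means)``.
    """
    if rule == "none":
        shift_ms = 0.0
    b_times = erp_b.time_axis_ms + shift_ms
    lo = max(erp_a.time_axis_ms[0], b_times[0])
    hi = min(erp_a.time_axis_ms[-1], b_times[-1])
    keep = (erp_a.time_axis_ms >= lo) & (erp_a.time_axis_ms <= hi)
    if not keep.any():
        raise ValueError(
            f"empty overlap after aligning with shift {shift_ms:.1f} ms")
    times = erp_a.time_axis_ms[keep]
    a = erp_a.subject_means[:, keep]
    b = np.stack([np.interp(times, b_times, row)
                  for row in erp_b.subject_means])
    return times, a, b


def pointwise_paired_test(subject_means_a: np.ndarray,
                          subject_means_b: np.ndarray,
                          time_axis_ms: np.ndarray,
                          tested_region: np.ndarray | None = None,
                          alpha: float = 0.05) -> StatResult:
    """Pointwise paired t-tests with BH-FDR across the tested region.

    ``tested_region`` is a boolean mask on the time axis (default: all
    timepoints after 0 ms). Outside the region t/p/q are NaN and the
    significance mask is False. Identical conditions give t = 0, p = 1.
    """
    a = np.asarray(subject_means_a, dtype=float)
    b = np.asarray(subject_means_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must contain the same subjects "
                         f"(shapes {a.shape} vs {b.shape})")
    if a.shape[0] < 3:
        raise ValueError("paired testing requires >= 3 subjects")
    if tested_region is None:
        tested_region = np.asarray(time_axis_ms) > 0
    tested_region = np.asarray(tested_region, dtype=bool)
    nt = a.shape[1]
    t = np.full(nt, np.nan)
    p = np.full(nt, np.nan)
    q = np.full(nt, np.nan)
    idx = np.flatnonzero(tested_region)
    if idx.size:
        diff = a[:, idx] - b[:, idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            tt, pp = sps.ttest_rel(a[:, idx], b[:, idx], axis=0)
        zero_var = np.all(diff == diff[0:1, :], axis=0)
        tt = np.where(zero_var & (diff[0] == 0), 0.0, tt)
        pp = np.where(zero_var & (diff[0] == 0), 1.0, pp)
        pp = np.where(np.isnan(pp) & zero_var, 0.0, pp)  # constant nonzero
        t[idx], p[idx] = tt, pp
        _, qq, _, _ = multipletests(pp, method="fdr_bh")
        q[idx] = qq
    sig = np.zeros(nt, dtype=bool)
    sig[idx] = q[idx] <= alpha
    return StatResult(time_axis_ms=np.asarray(time_axis_ms), t=t, p=p, q=q,
                      sig_mask=sig, tested_region=tested_region, alpha=alpha)


def woi_fraction_significant(stat: StatResult, woi: WOI) -> float:
    """Fraction of tested WOI timepoints that are significant."""
    inside = (stat.time_axis_ms >= woi.start_ms) \
        & (stat.time_axis_ms < woi.end_ms) & stat.tested_region
    if not inside.any():
        return np.nan
    return float(stat.sig_mask[inside].mean())


@dataclass
class ComparisonResult:
    comparison: int
    pair: tuple
    rule: str
    shift_ms: float
    stat: StatResult
    woi_fractions: dict = field(default_factory=dict)


def run_comparisons(erps: dict, mean_rt_ms: float,
                    mean_blink_latency_ms: dict, alpha: float = 0.05,
                    align: bool = True,
                    woi_catalogue: dict = None) -> list[ComparisonResult]:
    """Run the six planned comparisons on per-subject ERPs.

    ``erps`` maps epoch-type names (``SL-STND`` ... ``BL-TRGT``) to
    :class:`ERP`. ``mean_rt_ms`` and ``mean_blink_latency_ms`` (keys
    ``standard``/``target``) are the cohort's measured anchors for the
    shift rules. With ``align=False`` the mixed-locking comparisons are run
    on raw (unshifted) axes.
    """
    woi_catalogue = woi_catalogue or WOI_CATALOGUE
    missing = [k for k in EPOCH_TYPES if k not in erps]
    if missing:
        raise ValueError(f"missing epoch types: {missing}")
    results = []
    for comp_id, (name_a, name_b, rule, wois) in COMPARISONS.items():
        erp_a, erp_b = erps[name_a], erps[name_b]
        common = sorted(set(erp_a.subject_ids) & set(erp_b.subject_ids))
        if len(common) < 3:
            raise ValueError(
                f"comparison {comp_id}: only {len(common)} common subjects")
        ia = [erp_a.subject_ids.index(s) for s in common]
        ib = [erp_b.subject_ids.index(s) for s in common]
        sub_a = ERP(common, erp_a.subject_means[ia], erp_a.time_axis_ms,
                    erp_a.n_epochs, erp_a.epoch_type)
        sub_b = ERP(common, erp_b.subject_means[ib], erp_b.time_axis_ms,
                    erp_b.n_epochs, erp_b.epoch_type)
        if rule == "shift_by_mean_rt":
            shift = float(mean_rt_ms)
        elif rule.startswith("shift_by_mean_blink_latency"):
            shift = float(mean_blink_latency_ms[rule.split(":")[1]])
        else:
            shift = 0.0
        eff_rule = rule if align else "none"
        times, a, b = align_for_comparison(sub_a, sub_b, eff_rule, shift)
        stat = pointwise_paired_test(a, b, times, tested_region=times > 0,
                                     alpha=alpha)
        fractions = {w: woi_fraction_significant(stat, woi_catalogue[w])
                     for w in wois}
        results.append(ComparisonResult(
            comparison=comp_id, pair=(name_a, name_b), rule=eff_rule,
            shift_ms=shift if eff_rule != "none" else 0.0, stat=stat,
            woi_fractions=fractions))
    return results
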