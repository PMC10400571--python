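"""Ground-truthed synthetic visual-oddball EEG with blinks.

The generator emulates a classical visual oddball protocol: runs of 125
stimuli (80 % standards, 20 % targets, first two standards), 200 ms stimulus
duration, inter-trial interval uniform on [2, 3] s. Behaviour follows the
published statistics of the emulated study: targets are detected with a
98.4 % hit rate at 397.2 +/- 38.9 ms, 46 % of standard and 48 % of target
trials are followed by a blink, and blink latencies are Gamma-distributed
(right-skewed, positive support) around the configured means.

The recording is a linear forward mixture of event-locked sources — a
parietal P300 (larger for targets), a precuneal blink-related potential
(class-independent by construction), a response-locked motor potential, and
a large frontopolar corneo-retinal blink artifact — plus 1/f background
noise and white sensor noise. Scalp maps of the neural sources come from the
package's own spherical forward model, so equivalent-dipole fits of the
recovered components have a known ground truth.

Two latency presets resolve the anchoring of target-trial blinks: under
``stimulus_anchored`` they are timed from stimulus onset (mean 779 ms);
under ``response_anchored`` they are timed from each trial's button press
(mean 511 ms). Standard-trial blinks are always stimulus-timed (mean
595 ms).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .config import (BehaviourConfig, ConfigurationError, NoiseConfig,
                     ProtocolConfig)
from .dataio import Recording, validate_events, write_recording, write_table
from .dipolefit import HeadModel, forward_potential

# ---------------------------------------------------------------------------
# source model
# ---------------------------------------------------------------------------

ANCHORS = ("stimulus", "response", "blink")


@dataclass(frozen=True)
class KernelSpec:
    """Time course of a source, sampled on demand at any rate.

    ``gaussian_bump``: positive half-wave ``exp(-(t - center)^2 / 2 sigma^2)``
    truncated at ``4 sigma``; ``biphasic_blink``: a large positive lobe
    peaking at the anchor instant followed by a smaller negative rebound
    (total duration roughly 300 ms), mimicking the corneo-retinal artifact.
    """

    kind: str  # "gaussian_bump" | "biphasic_blink"
    center_ms: float = 0.0
    sigma_ms: float = 60.0
    rebound_fraction: float = 0.3
    rebound_delay_ms: float = 160.0
    rebound_sigma_ms: float = 75.0

    def sample(self, sampling_rate_hz: float) -> tuple[float, np.ndarray]:
        """Return ``(start_ms, values)``; unit peak (up to sampling)."""
        dt = 1000.0 / sampling_rate_hz
        if self.kind == "gaussian_bump":
            start = self.center_ms - 4 * self.sigma_ms
            stop = self.center_ms + 4 * self.sigma_ms
            t = np.arange(start, stop + dt / 2, dt)
            vals = np.exp(-0.5 * ((t - self.center_ms) / self.sigma_ms) ** 2)
        elif self.kind == "biphasic_blink":
            start = -4 * self.sigma_ms
            stop = self.rebound_delay_ms + 3 * self.rebound_sigma_ms
            t = np.arange(start, stop + dt / 2, dt)
            vals = (np.exp(-0.5 * (t / self.sigma_ms) ** 2)
                    - self.rebound_fraction
                    * np.exp(-0.5 * ((t - self.rebound_delay_ms)
                                     / self.rebound_sigma_ms) ** 2))
        else:
            raise ConfigurationError(f"unknown kernel kind {self.kind!r}")
        return float(t[0]), vals

    @property
    def duration_ms(self) -> float:
        start, _ = {"gaussian_bump": (self.center_ms - 4 * self.sigma_ms, 0),
                    "biphasic_blink": (-4 * self.sigma_ms, 0)}[self.kind]
        if self.kind == "gaussian_bump":
            return 8 * self.sigma_ms
        return 4 * self.sigma_ms + self.rebound_delay_ms \
            + 3 * self.rebound_sigma_ms


@dataclass
class Source:
    """One event-locked source of the forward model."""

    name: str
    spatial_map: np.ndarray  # per-channel gain, unit Euclidean norm
    kernel: KernelSpec
    anchor: str  # "stimulus" | "response" | "blink"
    amplitude_by_class: dict  # uV peak amplitude keyed by stimulus class

    def __post_init__(self):
        if self.anchor not in ANCHORS:
            raise ConfigurationError(f"anchor must be one of {ANCHORS}")
        self.spatial_map = np.asarray(self.spatial_map, dtype=float)
        norm = np.linalg.norm(self.spatial_map)
        if norm == 0:
            raise ConfigurationError("spatial map must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            self.spatial_map = self.spatial_map / norm


@dataclass
class SourceModel:
    sources: list
    dipole_positions_mm: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sources)


def _frontal_artifact_map(channel_names) -> np.ndarray:
    """Frontopolar-dominant corneo-retinal artifact topography."""
    weights = {"Fp1": 1.0, "Fp2": 1.0, "AFz": 0.45,
               "F7": 0.18, "F3": 0.18, "Fz": 0.18, "F4": 0.18, "F8": 0.18,
               "FC5": 0.06, "FC1": 0.06, "FC2": 0.06, "FC6": 0.06}
    m = np.asarray([weights.get(ch, 0.02) for ch in channel_names])
    return m / np.linalg.norm(m)


def _dipolar_map(position_mm, orientation, headmodel: HeadModel) -> np.ndarray:
    """Unit-norm scalp map of a dipole, signed so its largest entry > 0."""
    v = forward_potential(position_mm, orientation, headmodel)
    v = v / np.linalg.norm(v)
    if v[np.abs(v).argmax()] < 0:
        v = -v
    return v


#: True dipole positions (mm) of the neural sources; the P300 and BRP
#: generators both sit in the toy "precuneus" region with distinct
#: orientations, the motor source in the left motor region.
DEFAULT_DIPOLES = {
    "p300": ((0.0, -58.0, 44.0), (0.0, -0.80, 0.60)),
    "brp": ((0.0, -62.0, 36.0), (0.0, -0.20, 0.98)),
    "motor": ((-38.0, -18.0, 50.0), (-0.55, -0.26, 0.79)),
}


def default_source_model(protocol: ProtocolConfig | None = None,
                         headmodel: HeadModel | None = None) -> SourceModel:
    """The default four-source forward model.

    Source peak amplitudes (uV, before the unit-norm map projection): P300 8
    (standard) / 16 (target); BRP 18 for both classes (the
    class-independence of the blink-related response is built into the
    generator); motor 8; blink artifact 120, making the artifact at least
    five times any neural source at the frontopolar channels.
    """
    protocol = protocol or ProtocolConfig()
    headmodel = headmodel or HeadModel(channel_names=protocol.channel_names)
    maps = {name: _dipolar_map(pos, ori, headmodel)
            for name, (pos, ori) in DEFAULT_DIPOLES.items()}
    sources = [
        Source("p300", maps["p300"],
               KernelSpec("gaussian_bump", center_ms=400.0, sigma_ms=60.0),
               anchor="stimulus",
               amplitude_by_class={"standard": 8.0, "target": 16.0}),
        Source("brp", maps["brp"],
               KernelSpec("gaussian_bump", center_ms=300.0, sigma_ms=60.0),
               anchor="blink",
               amplitude_by_class={"standard": 18.0, "target": 18.0}),
        Source("motor", maps["motor"],
               KernelSpec("gaussian_bump", center_ms=50.0, sigma_ms=50.0),
               anchor="response",
               amplitude_by_class={"standard": 8.0, "target": 8.0}),
        Source("blink_artifact",
               _frontal_artifact_map(protocol.channel_names),
               KernelSpec("biphasic_blink", sigma_ms=55.0),
               anchor="blink",
               amplitude_by_class={"standard": 120.0, "target": 120.0}),
    ]
    return SourceModel(sources,
                       {k: np.asarray(v[0]) for k, v in
                        DEFAULT_DIPOLES.items()})


# ---------------------------------------------------------------------------
# schedule and behaviour
# ---------------------------------------------------------------------------

def build_stimulus_schedule(protocol: ProtocolConfig,
                            rng_seed: int) -> pd.DataFrame:
    """Random stimulus schedule for all runs (onsets run-relative, ms).

    Per run: exactly ``round(target_fraction * n)`` targets placed uniformly
    at random among the positions after the leading standards; successive
    onsets differ by the stimulus duration plus a uniform ITI draw; the run
    starts after one ITI-distributed lead-in.
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = protocol.iti_range_ms
    rows = []
    trial = 0
    for run in range(protocol.n_runs):
        n = protocol.n_stimuli_per_run
        n_targets = protocol.n_targets_per_run
        kinds = np.array(["standard"] * n, dtype=object)
        if n_targets:
            free = np.arange(protocol.n_leading_standards, n)
            if n_targets > free.size:
                raise ConfigurationError(
                    "not enough positions after the leading standards for "
                    f"{n_targets} targets")
            kinds[rng.choice(free, size=n_targets, replace=False)] = "target"
        onset = rng.uniform(lo, hi)
        for i in range(n):
            rows.append({"onset_ms": onset,
                         "duration_ms": protocol.stim_duration_ms,
                         "event_type": kinds[i],
                         "trial_index": trial,
                         "run_id": f"run{run + 1}"})
            onset += protocol.stim_duration_ms + rng.uniform(lo, hi)
            trial += 1
    schedule = pd.DataFrame(
        rows, columns=["onset_ms", "duration_ms", "event_type",
                       "trial_index", "run_id"])
    if len(schedule):
        validate_events(schedule)
    return schedule


def _gamma_draw(rng, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    shape = 1.0 / cv ** 2
    return float(rng.gamma(shape, mean * cv ** 2))


def sample_behaviour(schedule: pd.DataFrame, behaviour: BehaviourConfig,
                     rng_seed: int, trailing_limit_ms: float = 2000.0
                     ) -> pd.DataFrame:
    """Add response and blink events to a stimulus schedule.

    Each target receives a response with probability ``hit_rate`` at a
    truncated-normal (> 0) latency. Each stimulus receives at most one
    assigned blink with its class probability; the blink latency is a Gamma
    draw anchored to the stimulus (standards always; targets under the
    ``stimulus_anchored`` preset) or to the trial's own response (targets
    under ``response_anchored``; unresponded targets then get no blink). A
    blink drawn beyond the next stimulus onset of the same run (or beyond
    ``trailing_limit_ms`` after the last one) is redrawn at most 5 times and
    then dropped. Optionally, task-unrelated background blinks (trial_index
    -1) are inserted in the inter-trial gaps at ``background_blink_rate_hz``.
    """
    if len(schedule) == 0:
        return schedule.copy()
    rng = np.random.default_rng(rng_seed)
    response_anchored = behaviour.latency_preset == "response_anchored"
    rows = []
    for run_id, grp in schedule.groupby("run_id", sort=False):
        grp = grp.sort_values("onset_ms")
        onsets = grp["onset_ms"].to_numpy(float)
        limits = np.append(onsets[1:], onsets[-1] + trailing_limit_ms)
        last_blink = -np.inf
        for (_, stim), limit in zip(grp.iterrows(), limits):
            rows.append(stim.to_dict())
            onset = float(stim["onset_ms"])
            is_target = stim["event_type"] == "target"
            rt = None
            if is_target and rng.random() < behaviour.hit_rate:
                rt = rng.normal(behaviour.rt_mean_ms, behaviour.rt_sd_ms)
                while rt <= 0:
                    rt = rng.normal(behaviour.rt_mean_ms, behaviour.rt_sd_ms)
                rows.append({"onset_ms": onset + rt, "duration_ms": 0.0,
                             "event_type": "response",
                             "trial_index": stim["trial_index"],
                             "run_id": run_id})
            p_blink = (behaviour.blink_prob_target if is_target
                       else behaviour.blink_prob_standard)
            if rng.random() >= p_blink:
                continue
            if is_target and response_anchored:
                if rt is None:
                    continue  # no response to anchor the blink to
                anchor, mean = onset + rt, \
                    behaviour.blink_latency_mean_from_response_ms
            elif is_target:
                anchor, mean = onset, behaviour.blink_latency_mean_target_ms
            else:
                anchor, mean = onset, behaviour.blink_latency_mean_standard_ms
            t0 = None
            for _ in range(6):  # initial draw + at most 5 redraws
                cand = anchor + _gamma_draw(rng, mean,
                                            behaviour.blink_latency_cv)
                if cand < limit and \
                        cand - last_blink >= behaviour.blink_refractory_ms:
                    t0 = cand
                    break
            if t0 is None:
                continue
            last_blink = t0
            rows.append({"onset_ms": t0, "duration_ms": 0.0,
                         "event_type": "blink",
                         "trial_index": stim["trial_index"],
                         "run_id": run_id})
        if behaviour.background_blink_rate_hz > 0:
            for onset, limit in zip(onsets, limits):
                lo, hi = onset + 1700.0, limit - 200.0
                if hi <= lo:
                    continue
                n_bg = rng.poisson(
                    behaviour.background_blink_rate_hz * (hi - lo) / 1000.0)
                for t in sorted(rng.uniform(lo, hi, size=n_bg)):
                    rows.append({"onset_ms": t, "duration_ms": 0.0,
                                 "event_type": "blink", "trial_index": -1,
                                 "run_id": run_id})
    out = pd.DataFrame(rows).sort_values(
        ["run_id", "onset_ms"], kind="stable").reset_index(drop=True)
    return validate_events(out)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything injected into one rendered run."""

    events: pd.DataFrame  # full event table incl. blink and response rows
    true_source_maps: dict  # name -> per-channel mixing column (unit norm)
    true_dipole_positions: dict  # name -> (3,) mm
    duration_ms: float = 0.0

    def per_stimulus_frame(self) -> pd.DataFrame:
        """One row per stimulus: onset, type, trial, run, rt, blink T0."""
        stim = self.events[self.events["event_type"]
                           .isin(("standard", "target"))]
        aux = {t: {"rt_ms": np.nan, "blink_t0_ms": np.nan}
               for t in stim["trial_index"]}
        for _, row in self.events.iterrows():
            t = row["trial_index"]
            if t not in aux:
                continue
            if row["event_type"] == "response":
                aux[t]["rt_ms"] = row["onset_ms"] - float(
                    stim.loc[stim["trial_index"] == t, "onset_ms"].iloc[0])
            elif row["event_type"] == "blink":
                aux[t]["blink_t0_ms"] = row["onset_ms"]
        out = stim.loc[:, ["onset_ms", "event_type", "trial_index",
                           "run_id"]].copy()
        out = out.rename(columns={"run_id": "run"})
        out["rt_ms"] = [aux[t]["rt_ms"] for t in out["trial_index"]]
        out["blink_t0_ms"] = [aux[t]["blink_t0_ms"]
                              for t in out["trial_index"]]
        return out


def _pink_noise(rng, n: int, exponent: float, rms: float,
                n_channels: int = 1) -> np.ndarray:
    """Independent 1/f^exponent noise per channel, (n_channels, n), unit rms
    scaled to ``rms``. Uses an FFT-friendly padded length for speed."""
    if rms == 0 or n < 2:
        return np.zeros((n_channels, n))
    from scipy.fft import next_fast_len

    nf = next_fast_len(n)
    spec = np.fft.rfft(rng.standard_normal((n_channels, nf)), axis=-1)
    f = np.fft.rfftfreq(nf)
    f[0] = f[1]  # keep DC finite; it is demeaned below
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, nf, axis=-1)[:, :n]
    x -= x.mean(axis=-1, keepdims=True)
    return x * (rms / x.std(axis=-1, keepdims=True))


@lru_cache(maxsize=4)
def _background_headmodel(channel_names: tuple) -> "HeadModel":
    return HeadModel(channel_names=channel_names)


def _random_background_maps(rng, n_sources: int, channel_names) -> np.ndarray:
    """Unit-norm scalp maps of random intracranial dipoles, (n_ch, n_src)."""
    hm = _background_headmodel(tuple(channel_names))
    r_max = 0.9 * hm.brain_radius_mm
    maps = np.empty((len(channel_names), n_sources))
    for k in range(n_sources):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = r_max * rng.random() ** (1.0 / 3.0)
        ori = rng.standard_normal(3)
        ori /= np.linalg.norm(ori)
        g = forward_potential(radius * direction, ori, hm)
        maps[:, k] = g / np.linalg.norm(g)
    return maps


def _narrowband(rng, n: int, fs: float, center_hz: float,
                rms: float) -> np.ndarray:
    if rms == 0 or n < 2:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= np.exp(-0.5 * ((f - center_hz) / 1.0) ** 2)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    return x * (rms / x.std())


def _stimulus_class(events: pd.DataFrame) -> dict:
    stim = events[events["event_type"].isin(("standard", "target"))]
    return dict(zip(stim["trial_index"], stim["event_type"]))


def render_recording(events: pd.DataFrame, sources: SourceModel,
                     noise: NoiseConfig, protocol: ProtocolConfig,
                     rng_seed: int, subject_id: str = "synthetic",
                     ) -> tuple[Recording, GroundTruth]:
    """Render one run's event table into a multichannel recording (uV).

    The channel data are the sum over sources of the source kernel convolved
    with its anchor event train (scaled by the class amplitude and projected
    through the unit-norm spatial map), plus 1/f and sensor noise. Rendering
    is linear in the source amplitudes.
    """
    run_ids = set(events["run_id"]) if len(events) else {"run1"}
    if len(run_ids) > 1:
        raise ValueError("render_recording expects a single-run event table")
    run_id = next(iter(run_ids))
    fs = protocol.sampling_rate_hz
    stim = events[events["event_type"].isin(("standard", "target"))] \
        if len(events) else events
    end_ms = (stim["onset_ms"].max() + protocol.stim_duration_ms
              + protocol.tail_ms) if len(stim) else protocol.tail_ms
    end_ms = max(end_ms, float(events["onset_ms"].max()) + 1000.0) \
        if len(events) else end_ms
    n = int(np.ceil(end_ms / 1000.0 * fs))
    n_ch = protocol.n_channels
    data = np.zeros((n_ch, n))
    classes = _stimulus_class(events) if len(events) else {}

    min_gap_ms = np.inf
    if len(stim) > 1:
        gaps = np.diff(np.sort(stim["onset_ms"].to_numpy(float)))
        if gaps.size:
            min_gap_ms = gaps.min()

    for source in sources:
        if source.anchor == "stimulus":
            anchored = stim
        else:
            anchored = events[events["event_type"] ==
                              ("response" if source.anchor == "response"
                               else "blink")] if len(events) else events
        if len(anchored) == 0:
            continue
        if source.kernel.duration_ms > min_gap_ms:
            warnings.warn(
                f"kernel of source {source.name!r} "
                f"({source.kernel.duration_ms:.0f} ms) outlasts the minimum "
                f"inter-stimulus gap ({min_gap_ms:.0f} ms); events overlap",
                stacklevel=2)
        train = np.zeros(n)
        for _, ev in anchored.iterrows():
            idx = int(round(ev["onset_ms"] / 1000.0 * fs))
            if 0 <= idx < n:
                cls = classes.get(ev["trial_index"], "standard") \
                    if source.anchor != "stimulus" else ev["event_type"]
                train[idx] += source.amplitude_by_class.get(cls, 0.0)
        if not train.any():
            continue
        start_ms, kvals = source.kernel.sample(fs)
        conv = fftconvolve(train, kvals)
        shift = int(round(start_ms / 1000.0 * fs))
        trace = np.zeros(n)
        src_lo = max(0, -shift)
        dst_lo = max(0, shift)
        length = min(conv.size - src_lo, n - dst_lo)
        if length > 0:
            trace[dst_lo:dst_lo + length] = conv[src_lo:src_lo + length]
        data += np.outer(source.spatial_map, trace)

    rng = np.random.default_rng(rng_seed)
    if noise.pink_rms_uv > 0:
        if noise.spatial_structure == "dipolar":
            bg_maps = _random_background_maps(
                rng, noise.n_background_sources, protocol.channel_names)
            bg = bg_maps @ _pink_noise(rng, n, noise.pink_exponent, 1.0,
                                       n_channels=noise.n_background_sources)
            data += bg * (noise.pink_rms_uv / bg.std(axis=1).mean())
        else:
            data += _pink_noise(rng, n, noise.pink_exponent,
                                noise.pink_rms_uv, n_channels=n_ch)
    if noise.alpha_band:
        for ch in range(n_ch):
            data[ch] += _narrowband(rng, n, fs,
                                    noise.alpha_band["center_hz"],
                                    noise.alpha_band["rms_uv"])
    if noise.sensor_white_rms_uv:
        data += noise.sensor_white_rms_uv * rng.standard_normal((n_ch, n))

    recording = Recording(data=data, sampling_rate_hz=fs,
                          channel_names=protocol.channel_names,
                          subject_id=subject_id, run_id=run_id)
    truth = GroundTruth(
        events=events.reset_index(drop=True),
        true_source_maps={s.name: s.spatial_map.copy() for s in sources},
        true_dipole_positions={k: np.asarray(v) for k, v in
                               sources.dipole_positions_mm.items()},
        duration_ms=n / fs * 1000.0)
    return recording, truth


# ---------------------------------------------------------------------------
# subject-level convenience
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject_id: str
    recordings: list  # one Recording per run
    events: pd.DataFrame  # all runs, run-relative onsets
    truths: list  # one GroundTruth per run

    @property
    def ground_truth_events(self) -> pd.DataFrame:
        return self.events


def derive_seeds(master_seed: int, n: int, stream: str = "") -> list[int]:
    """Deterministic child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(
        [master_seed, int.from_bytes(stream.encode() or b"\0", "little")])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def simulate_subject(seed: int, subject_id: str = "sub-01",
                     protocol: ProtocolConfig | None = None,
                     behaviour: BehaviourConfig | None = None,
                     sources: SourceModel | None = None,
                     noise: NoiseConfig | None = None) -> SubjectData:
    """Simulate all runs of one subject (schedule, behaviour, rendering)."""
    protocol = protocol or ProtocolConfig()
    behaviour = behaviour or BehaviourConfig()
    sources = sources or default_source_model(protocol)
    noise = noise or NoiseConfig()
    sched_seed, behav_seed, render_seed = derive_seeds(seed, 3, subject_id)
    schedule = build_stimulus_schedule(protocol, sched_seed)
    events = sample_behaviour(schedule, behaviour, behav_seed,
                              trailing_limit_ms=protocol.tail_ms - 500.0)
    recordings, truths = [], []
    run_seeds = derive_seeds(render_seed, max(protocol.n_runs, 1), "render")
    for run in range(protocol.n_runs):
        run_id = f"run{run + 1}"
        run_events = events[events["run_id"] == run_id]
        rec, truth = render_recording(run_events, sources, noise, protocol,
                                      run_seeds[run], subject_id=subject_id)
        recordings.append(rec)
        truths.append(truth)
    return SubjectData(subject_id=subject_id, recordings=recordings,
                       events=events, truths=truths)


def write_subject(subject: SubjectData, out_dir) -> Path:
    """Persist a subject: per-run bundles, ground-truth TSV, true maps JSON."""
    out_dir = Path(out_dir) / subject.subject_id
    for rec, truth in zip(subject.recordings, subject.truths):
        write_recording(rec, truth.events, out_dir / rec.run_id)
        gt = truth.per_stimulus_frame()
        write_table(gt, out_dir / rec.run_id / "ground_truth.tsv")
    maps = {name: list(map(float, vec))
            for name, vec in subject.truths[0].true_source_maps.items()}
    dips = {name: list(map(float, pos))
            for name, pos in subject.truths[0].true_dipole_positions.items()}
    (out_dir / "truth.json").write_text(json.dumps(
        {"true_source_maps": maps, "true_dipole_positions": dips}, indent=1))
    return out_dir
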