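"""Generator tests: protocol arithmetic, behaviour sampling, rendering."""

import numpy as np
import pandas as pd
import pytest

from blinkerp.config import (BehaviourConfig, ConfigurationError,
                             ProtocolConfig)
from blinkerp.synthio import (build_stimulus_schedule,
                              default_source_model, render_recording,
                              sample_behaviour, simulate_subject)


class TestSchedule:
    def test_default_counts_and_leading_standards(self):
        sched = build_stimulus_schedule(ProtocolConfig(), rng_seed=1)
        counts = sched["event_type"].value_counts()
        assert counts["standard"] == 300 and counts["target"] == 75
        for _, run in sched.groupby("run_id"):
            first = run.sort_values("onset_ms")["event_type"].iloc[:2]
            assert (first == "standard").all()

    def test_empty_protocol_gives_empty_table(self):
        sched = build_stimulus_schedule(
            ProtocolConfig(n_stimuli_per_run=0, n_leading_standards=0),
            rng_seed=0)
        assert len(sched) == 0

    def test_inter_onset_gaps_are_stimulus_plus_iti(self):
        sched = build_stimulus_schedule(ProtocolConfig(), rng_seed=7)
        gaps = np.concatenate([
            np.diff(run.sort_values("onset_ms")["onset_ms"].to_numpy())
            for _, run in sched.groupby("run_id")])
        assert gaps.size == 372  # 124 gaps per run x 3 runs
        assert gaps.min() >= 2200.0 and gaps.max() <= 3200.0

    def test_deterministic_given_seed(self):
        a = build_stimulus_schedule(ProtocolConfig(), rng_seed=5)
        b = build_stimulus_schedule(ProtocolConfig(), rng_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_fraction_raises(self):
        with pytest.raises(ConfigurationError):
            ProtocolConfig(target_fraction=0.21)  # 0.21 * 125 not integer


class TestBehaviour:
    def test_degenerate_rt_distribution(self):
        sched = build_stimulus_schedule(ProtocolConfig(), 3)
        ev = sample_behaviour(sched, BehaviourConfig(hit_rate=1.0,
                                                     rt_sd_ms=0.0), 4)
        resp = ev[ev["event_type"] == "response"]
        stim = ev[ev["event_type"] == "target"]
        assert len(resp) == len(stim) == 75
        onset = dict(zip(stim["trial_index"], stim["onset_ms"]))
        rts = [r["onset_ms"] - onset[r["trial_index"]]
               for _, r in resp.iterrows()]
        assert np.allclose(rts, 397.2)

    def test_zero_blink_probability(self):
        sched = build_stimulus_schedule(ProtocolConfig(), 3)
        ev = sample_behaviour(sched, BehaviourConfig(
            blink_prob_standard=0.0, blink_prob_target=0.0), 4)
        assert (ev["event_type"] == "blink").sum() == 0

    def test_blink_fraction_matches_configured_rate(self):
        # ~10 000 standard trials pooled over seeded sessions
        protocol = ProtocolConfig()
        n_std = n_blink = 0
        for seed in range(34):
            sched = build_stimulus_schedule(protocol, 100 + seed)
            ev = sample_behaviour(sched, BehaviourConfig(), 200 + seed)
            std_trials = set(
                ev.loc[ev["event_type"] == "standard", "trial_index"])
            blinks = ev[ev["event_type"] == "blink"]
            n_std += len(std_trials)
            n_blink += blinks["trial_index"].isin(std_trials).sum()
        assert n_std >= 10000
        assert abs(100.0 * n_blink / n_std - 46.0) < 2.0

    def test_generative_standard_latency_mean(self):
        lats = []
        for seed in range(16):
            sched = build_stimulus_schedule(ProtocolConfig(), 300 + seed)
            ev = sample_behaviour(sched, BehaviourConfig(), 400 + seed)
            stim = ev[ev["event_type"] == "standard"]
            onset = dict(zip(stim["trial_index"], stim["onset_ms"]))
            for _, b in ev[ev["event_type"] == "blink"].iterrows():
                if b["trial_index"] in onset:
                    lats.append(b["onset_ms"] - onset[b["trial_index"]])
        lats = np.asarray(lats)
        assert lats.size >= 2000
        assert abs(lats.mean() - 595.0) < 3 * lats.std() / np.sqrt(lats.size)

    def test_response_anchored_preset_skips_unresponded_targets(self):
        sched = build_stimulus_schedule(ProtocolConfig(), 3)
        ev = sample_behaviour(sched, BehaviourConfig(
            hit_rate=0.0, latency_preset="response_anchored",
            blink_prob_standard=0.0, blink_prob_target=1.0), 4)
        assert (ev["event_type"] == "blink").sum() == 0


class TestRendering:
    def test_null_signal(self, quiet_noise):
        protocol = ProtocolConfig(n_runs=1, n_stimuli_per_run=5,
                                  n_leading_standards=1)
        sched = build_stimulus_schedule(protocol, 1)
        sources = default_source_model(protocol)
        for s in sources:
            s.amplitude_by_class = {k: 0.0 for k in s.amplitude_by_class}
        rec, _ = render_recording(sched, sources, quiet_noise, protocol, 0)
        assert np.all(rec.data == 0.0)

    def test_single_blink_projects_kernel_on_frontopolar(self, quiet_noise):
        protocol = ProtocolConfig(n_runs=1, n_stimuli_per_run=0,
                                  n_leading_standards=0)
        t0 = 3000.0
        events = pd.DataFrame([{"onset_ms": t0, "duration_ms": 0.0,
                                "event_type": "blink", "trial_index": -1,
                                "run_id": "run1"}])
        sources = default_source_model(protocol)
        for s in sources:  # isolate the artifact source
            if s.name != "blink_artifact":
                s.amplitude_by_class = {k: 0.0 for k in s.amplitude_by_class}
        rec, truth = render_recording(events, sources, quiet_noise,
                                      protocol, 0)
        blink = next(s for s in sources if s.name == "blink_artifact")
        fp = rec.channel("Fp1")
        peak_sample = int(np.argmax(fp))
        injected = int(round(t0 / 1000.0 * protocol.sampling_rate_hz))
        assert abs(peak_sample - injected) <= 1
        # trace equals kernel x map gain x amplitude
        start_ms, kvals = blink.kernel.sample(protocol.sampling_rate_hz)
        gain = blink.spatial_map[rec.channel_names.index("Fp1")] * 120.0
        lo = injected + int(round(start_ms / 1000.0
                                  * protocol.sampling_rate_hz))
        np.testing.assert_allclose(fp[lo:lo + kvals.size], kvals * gain,
                                   atol=1e-7)

    def test_rendering_is_linear_in_amplitude(self, quiet_noise):
        protocol = ProtocolConfig(n_runs=1, n_stimuli_per_run=10)
        sched = build_stimulus_schedule(protocol, 2)
        ev = sample_behaviour(sched, BehaviourConfig(), 3)

        def render(scale):
            sources = default_source_model(protocol)
            for s in sources:
                if s.name == "p300":
                    s.amplitude_by_class = {
                        k: v * scale for k, v in s.amplitude_by_class.items()}
            rec, _ = render_recording(ev, sources, quiet_noise, protocol, 0)
            return rec.data

        base = render(1.0)
        only_others = render(0.0)
        doubled = render(2.0)
        np.testing.assert_allclose(doubled - only_others,
                                   2.0 * (base - only_others), atol=1e-9)

    def test_frontopolar_louder_than_parietal_by_default(
            self, default_subject):
        rec = default_subject.recordings[0]
        assert rec.channel("Fp1").std() > rec.channel("Pz").std()

    def test_bit_reproducible_given_seed(self):
        protocol = ProtocolConfig(n_runs=1, n_stimuli_per_run=10)
        a = simulate_subject(77, "s", protocol=protocol)
        b = simulate_subject(77, "s", protocol=protocol)
        assert np.array_equal(a.recordings[0].data, b.recordings[0].data)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_ground_truth_blinks_inside_recording(self, default_subject):
        for rec, truth in zip(default_subject.recordings,
                              default_subject.truths):
            blinks = truth.events[truth.events["event_type"] == "blink"]
            assert (blinks["onset_ms"] >= 0).all()
            assert (blinks["onset_ms"] < rec.duration_ms).all()

    def test_per_stimulus_truth_frame(self, default_subject):
        frame = default_subject.truths[0].per_stimulus_frame()
        assert len(frame) == 125
        responded = frame[frame["rt_ms"].notna()]
        assert (responded["event_type"] == "target").all()
        assert (responded["rt_ms"] > 0).all()
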