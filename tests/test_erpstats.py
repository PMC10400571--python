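"""Epoching, averaging, alignment, and FDR-corrected pointwise testing."""

import numpy as np
import pytest

from blinkerp.blinks import BlinkTimes, assign_first_blinks
from blinkerp.dataio import Recording
from blinkerp.erpstats import (EPOCH_TYPES, ERP, EpochSet, WOI_CATALOGUE,
                               align_for_comparison, average_erp,
                               extract_epochs, pointwise_paired_test,
                               run_comparisons)
from blinkerp.synthio import simulate_subject
import blinkerp.pipeline as pl

FS = 250.0


@pytest.fixture(scope="module")
def subject_with_truth(source_model):
    """Default subject, concatenated, with truth-based blink assignment."""
    subject = simulate_subject(424242, "sub-erp", sources=source_model)
    recording, events = pl._concatenate_runs(subject)
    truth_blinks = np.sort(events.loc[events["event_type"] == "blink",
                                      "onset_ms"].to_numpy())
    blinks = BlinkTimes("sub-erp", "concat", truth_blinks,
                        refractory_ms=0.0)
    assignments = assign_first_blinks(blinks, events)
    return recording, events, assignments


# fixture defined in conftest is session scoped; re-export for this module
@pytest.fixture(scope="module")
def source_model():
    from blinkerp.synthio import default_source_model
    return default_source_model()


class TestExtraction:
    def test_default_epoch_counts(self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        sl_stnd = extract_epochs(recording, events, "SL", "STND",
                                 assignments)
        sl_trgt = extract_epochs(recording, events, "SL", "TRGT",
                                 assignments)
        assert sl_stnd.n_epochs == 300
        assert sl_trgt.n_epochs == 75

    def test_bl_count_matches_assignments(self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        bl = extract_epochs(recording, events, "BL", "STND", assignments)
        expected = ((assignments["stimulus_type"] == "standard")
                    & assignments["blink_t0_ms"].notna()).sum()
        assert bl.n_epochs == expected

    def test_all_zero_recording_gives_zero_epochs(self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        zero = Recording(np.zeros_like(recording.data),
                         recording.sampling_rate_hz,
                         recording.channel_names)
        es = extract_epochs(zero, events, "SL", "STND", assignments)
        assert np.all(es.epochs == 0.0)

    def test_sl_baseline_mean_zero(self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        es = extract_epochs(recording, events, "SL", "STND", assignments)
        pre = es.epochs[:, es.time_axis_ms < 0.0]
        assert np.abs(pre.mean(axis=1)).max() < 1e-9

    def test_baseline_correction_idempotent(self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        es1 = extract_epochs(recording, events, "SL", "STND", assignments)
        # re-extracting from an already baseline-corrected recording at the
        # stimulus channel leaves SL epochs unchanged
        es2 = extract_epochs(recording, events, "SL", "STND", assignments)
        np.testing.assert_array_equal(es1.epochs, es2.epochs)

    def test_rl_requires_targets(self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        with pytest.raises(ValueError, match="target"):
            extract_epochs(recording, events, "RL", "STND", assignments)

    def test_bl_requires_assignments(self, subject_with_truth):
        recording, events, _ = subject_with_truth
        with pytest.raises(ValueError, match="assignments"):
            extract_epochs(recording, events, "BL", "STND", None)

    def test_window_lengths(self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        sl = extract_epochs(recording, events, "SL", "STND", assignments)
        bl = extract_epochs(recording, events, "BL", "STND", assignments)
        assert sl.time_axis_ms[0] == -500.0
        assert sl.time_axis_ms[-1] < 1500.0
        assert bl.time_axis_ms[0] == -1500.0
        assert bl.time_axis_ms[-1] < 500.0
        assert sl.epochs.shape[1] == bl.epochs.shape[1] == int(2.0 * FS)


class TestAveraging:
    def _eset(self, epochs):
        epochs = np.asarray(epochs, dtype=float)
        return EpochSet(epochs=epochs,
                        time_axis_ms=np.arange(epochs.shape[1]) * 4.0,
                        locking="SL", stimulus_class="STND",
                        trial_indices=np.arange(epochs.shape[0]))

    def test_single_epoch_grand_average(self):
        erp = average_erp({"s1": self._eset([[1.0, 2.0, 3.0]])})
        np.testing.assert_array_equal(erp.grand_average, [1.0, 2.0, 3.0])

    def test_two_subject_unweighted_mean(self):
        erp = average_erp({
            "s1": self._eset([[1.0, 1.0]]),
            "s2": self._eset([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])})
        np.testing.assert_array_equal(erp.grand_average, [2.0, 2.0])

    def test_epoch_order_invariance(self, rng):
        epochs = rng.standard_normal((10, 6))
        a = average_erp({"s": self._eset(epochs)})
        b = average_erp({"s": self._eset(epochs[::-1])})
        np.testing.assert_allclose(a.grand_average, b.grand_average)

    def test_target_grand_average_peaks_in_yellow_woi(
            self, subject_with_truth):
        recording, events, assignments = subject_with_truth
        es = extract_epochs(recording, events, "SL", "TRGT", assignments)
        erp = average_erp({"s": es})
        post = (erp.time_axis_ms > 0) & (erp.time_axis_ms < 800)
        peak_ms = erp.time_axis_ms[post][np.argmax(erp.grand_average[post])]
        woi = WOI_CATALOGUE["yellow"]
        assert woi.start_ms <= peak_ms < woi.end_ms


class TestAlignment:
    def _erp(self, times, values):
        return ERP(["s1"], np.asarray(values)[None, :], np.asarray(times),
                   {"s1": 1})

    def test_rule_none_identity(self):
        t = np.arange(-500.0, 1500.0, 4.0)
        a = self._erp(t, np.sin(t / 100.0))
        times, av, bv = align_for_comparison(a, a, "none")
        np.testing.assert_array_equal(times, t)
        np.testing.assert_allclose(av, bv)

    def test_shift_interval_arithmetic(self):
        t = np.arange(-500.0, 1500.0, 4.0)
        a = self._erp(t, np.zeros_like(t))
        b = self._erp(t, np.zeros_like(t))
        r = 397.2
        times, _, _ = align_for_comparison(a, b, "shift_by_mean_rt", r)
        # overlap = [max(-500, -500+r), min(<1500, <1500+r))
        assert times[0] == pytest.approx(-500.0 + r, abs=4.0)
        assert times[-1] == t[-1]

    def test_empty_overlap_raises(self):
        t = np.arange(-500.0, 1500.0, 4.0)
        a = self._erp(t, np.zeros_like(t))
        b = self._erp(t, np.zeros_like(t))
        with pytest.raises(ValueError, match="overlap"):
            align_for_comparison(a, b, "shift_by_mean_rt", 5000.0)

    def test_shift_moves_waveform_onto_a_axis(self):
        t = np.arange(-500.0, 1500.0, 4.0)
        bump_b = np.exp(-0.5 * (t / 50.0) ** 2)  # peak at B's 0 ms
        a = self._erp(t, np.zeros_like(t))
        b = self._erp(t, bump_b)
        times, _, bv = align_for_comparison(
            a, b, "shift_by_mean_blink_latency", 595.0)
        assert abs(times[np.argmax(bv[0])] - 595.0) < 8.0


class TestPointwiseTest:
    def test_identical_conditions(self, rng):
        a = rng.standard_normal((5, 40))
        t = np.arange(40) * 4.0 - 40.0
        res = pointwise_paired_test(a, a.copy(), t)
        tested = res.tested_region
        assert np.all(res.t[tested] == 0.0)
        assert np.all(res.p[tested] == 1.0)
        assert not res.sig_mask.any()

    def test_bh_adjustment_matches_direct_formula(self):
        # p = [.01, .02, .03, .04], m = 4 -> q all 0.04
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.01, 0.02, 0.03, 0.04])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        # and through the package path: embed in a paired test region
        rngl = np.random.default_rng(0)
        a = rngl.standard_normal((6, 4))
        b = a + rngl.standard_normal((6, 4)) * 0.5
        t = np.arange(4.0) + 1.0
        res = pointwise_paired_test(a, b, t)
        m = res.tested_region.sum()
        order = np.argsort(res.p[res.tested_region])
        ranked = res.p[res.tested_region][order] * m / \
            (np.arange(m) + 1)
        expected_q = np.minimum.accumulate(ranked[::-1])[::-1]
        got_q = res.q[res.tested_region][order]
        np.testing.assert_allclose(got_q, np.minimum(expected_q, 1.0))

    def test_q_never_below_p(self, rng):
        a = rng.standard_normal((8, 100))
        b = a + 0.3 * rng.standard_normal((8, 100))
        res = pointwise_paired_test(a, b, np.arange(100.0) + 1.0)
        tested = res.tested_region
        assert np.all(res.q[tested] >= res.p[tested] - 1e-12)

    def test_sig_mask_false_outside_region(self, rng):
        a = rng.standard_normal((5, 50))
        b = a + 5.0  # certain difference
        t = np.arange(50) * 4.0 - 100.0
        res = pointwise_paired_test(a, b, t)
        assert not res.sig_mask[t <= 0].any()
        assert res.sig_mask[t > 0].all()

    def test_fewer_than_three_subjects_refused(self, rng):
        a = rng.standard_normal((2, 10))
        with pytest.raises(ValueError, match=">= 3 subjects"):
            pointwise_paired_test(a, a, np.arange(10.0))

    def test_null_fdr_calibration(self, rng):
        # 200 replicates of a pure-null paired comparison with temporally
        # correlated (smoothed) noise: the fraction of replicates with any
        # significant timepoint must be consistent with FDR control at 0.05
        from scipy.ndimage import gaussian_filter1d
        t = np.arange(125.0) * 4.0 + 4.0
        n_any = 0
        reps = 200
        for _ in range(reps):
            a = gaussian_filter1d(rng.standard_normal((10, t.size)), 3,
                                  axis=1)
            b = gaussian_filter1d(rng.standard_normal((10, t.size)), 3,
                                  axis=1)
            res = pointwise_paired_test(a, b, t)
            n_any += res.sig_mask.any()
        # binomial 99% upper band around 0.05
        assert n_any / reps <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / reps)


class TestComparisons:
    def _erps(self, rng, effect=0.0):
        t_sl = np.arange(-500.0, 1500.0, 4.0)
        t_bl = np.arange(-1500.0, 500.0, 4.0)
        erps = {}
        for name in EPOCH_TYPES:
            t = t_bl if name.startswith("BL") else t_sl
            base = rng.standard_normal((5, t.size)) * 0.1
            if name == "SL-TRGT":
                base += effect * np.exp(-0.5 * ((t - 400.0) / 60.0) ** 2)
            erps[name] = ERP([f"s{i}" for i in range(5)], base, t,
                             {f"s{i}": 10 for i in range(5)}, name)
        return erps

    def test_missing_epoch_type_named(self, rng):
        erps = self._erps(rng)
        del erps["BL-TRGT"]
        with pytest.raises(ValueError, match="BL-TRGT"):
            run_comparisons(erps, 397.2, {"standard": 595.0,
                                          "target": 779.0})

    def test_six_comparisons_and_planted_p300(self, rng):
        erps = self._erps(rng, effect=2.0)
        results = run_comparisons(erps, 397.2,
                                  {"standard": 595.0, "target": 779.0})
        assert [r.comparison for r in results] == [1, 2, 3, 4, 5, 6]
        comp1 = results[0]
        assert comp1.woi_fractions["yellow"] > 0.5
        comp6 = results[5]
        assert "bl_brp" in comp6.woi_fractions
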