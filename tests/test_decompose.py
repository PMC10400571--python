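"""Rank estimation, ICA recovery, component labelling, backprojection."""

import inspect

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from blinkerp.channels import DEFAULT_CHANNELS
from blinkerp.decompose import (ICDecomposition, backproject,
                                classify_components, estimate_rank, run_ica)


class TestRank:
    def test_full_rank_noise(self, rng):
        data = rng.standard_normal((34, 3000))
        assert estimate_rank(data) == 34

    def test_duplicated_channel_reduces_rank(self, rng):
        data = rng.standard_normal((34, 3000))
        data35 = np.vstack([data, data[0]])
        assert data35.shape[0] == 35
        assert estimate_rank(data35) == 34

    def test_default_tolerance(self):
        sig = inspect.signature(estimate_rank)
        assert sig.parameters["tolerance"].default == 1e-10

    def test_constant_data_rank_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_rank(np.ones((3, 100))) == 0


def _super_gaussian_sources(rng, n_sources, n_samples):
    s = np.zeros((n_sources, n_samples))
    for k in range(n_sources):
        idx = rng.integers(0, n_samples, n_samples // 50)
        s[k, idx] = rng.laplace(size=idx.size) * 5
        s[k] = gaussian_filter1d(s[k], 4)
    return s


class TestICA:
    def test_recovers_mixed_super_gaussian_sources(self, rng):
        s = _super_gaussian_sources(rng, 3, 20000)
        mix = rng.standard_normal((34, 3))
        data = mix @ s
        dec = run_ica(data, n_components=3, rng_seed=0,
                      sampling_rate_hz=250.0)
        # greedy match by max |corr| against the known sources
        corr = np.corrcoef(np.vstack([s, dec.sources]))[:3, 3:]
        matched = set()
        for k in range(3):
            j = int(np.argmax(np.abs(corr[k])))
            assert abs(corr[k, j]) > 0.95
            matched.add(j)
        assert len(matched) == 3

    def test_identity_mixing_gives_signed_permutation(self, rng):
        s = _super_gaussian_sources(rng, 4, 20000)
        dec = run_ica(s, n_components=4, rng_seed=1, sampling_rate_hz=250.0)
        # mixing x unmixing is identity; mixing should be a signed
        # permutation up to scale
        g = dec.unmixing @ np.eye(4)
        g = g / np.abs(g).max(axis=1, keepdims=True)
        binary = np.abs(g) > 0.5
        assert (binary.sum(axis=0) == 1).all()
        assert (binary.sum(axis=1) == 1).all()

    def test_requesting_more_components_than_rank_raises(self, rng):
        data = rng.standard_normal((4, 1000))
        data = np.vstack([data, data[0]])  # rank 4, 5 channels
        with pytest.raises(ValueError, match="rank"):
            run_ica(data, n_components=5, rng_seed=0,
                    sampling_rate_hz=100.0)

    def test_sources_zero_mean_and_reconstruction(self, rng):
        data = rng.standard_normal((6, 5000)) + 3.0
        dec = run_ica(data, rng_seed=2, sampling_rate_hz=100.0)
        assert np.abs(dec.sources.mean(axis=1)).max() < 1e-8
        centred = data - data.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(dec.rank_reduced_data(), centred,
                                   atol=1e-8)

    def test_deterministic_given_seed(self, rng):
        data = rng.standard_normal((5, 4000))
        a = run_ica(data, rng_seed=9, sampling_rate_hz=100.0)
        b = run_ica(data, rng_seed=9, sampling_rate_hz=100.0)
        np.testing.assert_array_equal(a.unmixing, b.unmixing)


def _decomposition_with(maps, traces, fs=250.0):
    mixing = np.stack(maps, axis=1)
    unmixing = np.linalg.pinv(mixing)
    sources = np.stack(traces)
    return ICDecomposition(
        unmixing=unmixing, mixing=mixing, sources=sources,
        channel_names=DEFAULT_CHANNELS, sampling_rate_hz=fs,
        channel_means=np.zeros(len(DEFAULT_CHANNELS)))


class TestClassifier:
    def _frontal_map(self):
        m = np.full(34, 0.02)
        m[DEFAULT_CHANNELS.index("Fp1")] = 1.0
        m[DEFAULT_CHANNELS.index("Fp2")] = 0.9
        return m / np.linalg.norm(m)

    def _parietal_map(self):
        m = np.full(34, 0.05)
        for ch in ("P3", "Pz", "P4", "POz", "CP1", "CP2"):
            m[DEFAULT_CHANNELS.index(ch)] = 0.9
        return m / np.linalg.norm(m)

    def test_blink_sinusoid_and_noise_components(self, rng):
        fs = 250.0
        n = int(fs * 120)
        blink_trace = np.zeros(n)
        peaks = np.arange(500, n - 500, int(fs * 4))  # 15 blinks / min
        blink_trace[peaks] = 60.0
        blink_trace = gaussian_filter1d(blink_trace, 12)
        blink_trace += 0.1 * rng.standard_normal(n)
        sinusoid = np.sin(2 * np.pi * 10.0 * np.arange(n) / fs)
        noise = rng.standard_normal(n)
        flat_map = np.ones(34) / np.sqrt(34)
        dec = _decomposition_with(
            [self._frontal_map(), self._parietal_map(), flat_map],
            [blink_trace, sinusoid, noise], fs)
        labels = classify_components(dec)
        assert labels == ["blink", "brain", "other"]

    def test_labels_are_a_partition(self, rng):
        maps = [rng.standard_normal(34) for _ in range(5)]
        maps = [m / np.linalg.norm(m) for m in maps]
        traces = [rng.standard_normal(5000) for _ in range(5)]
        dec = _decomposition_with(maps, traces)
        labels = classify_components(dec)
        assert len(labels) == 5
        assert all(lab in ("brain", "blink", "eye_other", "muscle", "other")
                   for lab in labels)


class TestBackprojection:
    @pytest.fixture()
    def dec(self, rng):
        data = rng.standard_normal((8, 6000))
        return run_ica(data, rng_seed=3, sampling_rate_hz=100.0)

    def test_all_components_reproduce_rank_reduced_data(self, dec):
        full = backproject(dec, list(range(dec.n_components)))
        np.testing.assert_allclose(full.data, dec.rank_reduced_data(),
                                   atol=1e-9)

    def test_partition_additivity(self, dec):
        a = backproject(dec, [0, 1, 2]).data
        b = backproject(dec, [3, 4, 5, 6, 7]).data
        both = backproject(dec, list(range(8))).data
        np.testing.assert_allclose(a + b, both, atol=1e-9)

    def test_empty_subset_raises(self, dec):
        with pytest.raises(ValueError, match="non-empty"):
            backproject(dec, [])

    def test_blink_subset_recovers_artifact_noise_free(
            self, source_model, quiet_noise):
        from blinkerp.config import ProtocolConfig
        from blinkerp.synthio import simulate_subject
        protocol = ProtocolConfig(n_runs=1, n_stimuli_per_run=25)
        subj = simulate_subject(5150, "s", protocol=protocol,
                                noise=quiet_noise)
        rec = subj.recordings[0]
        dec = run_ica(rec, n_components=4, rng_seed=0)
        classify_components(dec)
        from blinkerp.decompose import blink_component
        b = blink_component(dec)
        assert b is not None
        proj = backproject(dec, [b])
        truth = subj.truths[0]
        blinks = truth.events[truth.events["event_type"] == "blink"]
        assert len(blinks) > 0
        # the frontopolar channel is dominated by the injected artifact,
        # so the blink component alone must reproduce it
        fp_idx = rec.channel_names.index("Fp1")
        r = np.corrcoef(proj.data[fp_idx], rec.channel("Fp1"))[0, 1]
        assert r > 0.99
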