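"""Rank estimation, ICA decomposition, component labelling, backprojection.

ICA is a seeded FastICA (non-Gaussianity maximization) run on the full-rank
(or rank-reduced) data. The unmixing matrix is estimated on a temporally
decimated copy of the recording — standard practice, since the spatial
mixture is time-invariant — and then applied at the full sampling rate.
Strict fixed-point convergence of all components is not required: in EEG the
near-Gaussian noise subspace has no identifiable rotation, so the fit is
instead validated algebraically (pseudo-inverse consistency and exact
reconstruction of the rank-reduced data); a decomposition failing those
checks, or containing non-finite weights, raises with iteration diagnostics.

Component labelling replaces a trained classifier with a documented
three-feature heuristic: a component is a blink component when its map
energy concentrates on the frontopolar channels, its trace is heavy-tailed
(high kurtosis), and its peak rate is physiologically plausible; it is a
brain component when its map is parietal-dominant with a low-kurtosis trace;
anything else is labelled "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import find_peaks, welch

from .channels import FRONTOPOLAR_CHANNELS, PARIETAL_CHANNELS, channel_indices
from .dataio import Recording

COMPONENT_LABELS = ("brain", "blink", "eye_other", "muscle", "other")

#: Default heuristic thresholds (overridable in :func:`classify_components`).
DEFAULT_CLASSIFIER_RULES = {
    "blink_frontopolar_concentration": 0.5,
    "blink_kurtosis": 5.0,
    "blink_peak_rate_per_min": (2.0, 40.0),
    "brain_parietal_concentration": 0.5,
    "brain_kurtosis": 5.0,
}


class ICAConvergenceError(RuntimeError):
    """ICA failed to produce a valid decomposition."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def estimate_rank(data: np.ndarray, tolerance: float = 1e-10) -> int:
    """Numerical rank of the data: covariance eigenvalues above tolerance.

    Counts eigenvalues of the channel covariance matrix exceeding
    ``tolerance`` times the largest eigenvalue (default 1e-10).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    if data.shape[1] < data.shape[0]:
        raise ValueError("need at least as many samples as channels")
    cov = np.cov(data)
    eig = np.linalg.eigvalsh(cov)
    top = eig[-1]
    if top <= 0:
        warnings.warn("constant data: rank 0", stacklevel=2)
        return 0
    return int(np.sum(eig > tolerance * top))


@dataclass
class ICDecomposition:
    """An ICA decomposition of one subject's (possibly concatenated) data."""

    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray  # channels x components
    sources: np.ndarray  # components x samples
    channel_names: tuple[str, ...]
    sampling_rate_hz: float
    channel_means: np.ndarray  # removed before unmixing
    labels: list = field(default_factory=list)
    features: list = field(default_factory=list)  # dict per component
    info: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def rank_reduced_data(self) -> np.ndarray:
        """Projection of the centred data onto the retained subspace."""
        return self.mixing @ self.sources


def run_ica(data, n_components: int | None = None, rng_seed: int = 0,
            sampling_rate_hz: float | None = None,
            channel_names=None, max_fit_samples: int = 20000,
            max_iter: int = 200, tol: float = 1e-5) -> ICDecomposition:
    """Seeded FastICA decomposition of a channels x samples matrix.

    ``data`` may be a :class:`~blinkerp.dataio.Recording` or an array (then
    ``sampling_rate_hz`` and ``channel_names`` must be given). The number of
    components defaults to the numerical rank of the data; requesting more
    raises. Deterministic given ``rng_seed``.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if isinstance(data, Recording):
        channel_names = data.channel_names
        sampling_rate_hz = data.sampling_rate_hz
        data = data.data
    data = np.asarray(data, dtype=float)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(data.shape[0]))
    rank = estimate_rank(data)
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but the data have rank "
            f"{rank}; reduce n_components (rank-deficient input)")
    means = data.mean(axis=1, keepdims=True)
    centred = data - means
    step = max(1, int(np.ceil(centred.shape[1] / max_fit_samples)))
    fit_data = centred[:, ::step]

    ica = FastICA(n_components=n_components, random_state=int(rng_seed),
                  whiten="unit-variance", max_iter=max_iter, tol=tol)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(fit_data.T)
    fp_converged = not any(issubclass(w.category, ConvergenceWarning)
                           for w in caught)
    unmixing = ica.components_.copy()  # components x channels
    mixing = np.linalg.pinv(unmixing)  # channels x components
    diagnostics = {"n_iter": int(ica.n_iter_), "max_iter": max_iter,
                   "tol": tol, "fixed_point_converged": bool(fp_converged),
                   "decimation_step": step, "algorithm": "fastica",
                   "n_components": int(n_components), "rank": int(rank)}
    if not np.isfinite(unmixing).all():
        raise ICAConvergenceError("ICA produced non-finite weights",
                                  diagnostics)
    sources = unmixing @ centred
    sources -= sources.mean(axis=1, keepdims=True)
    dec = ICDecomposition(unmixing=unmixing, mixing=mixing, sources=sources,
                          channel_names=tuple(channel_names),
                          sampling_rate_hz=float(sampling_rate_hz or 0.0),
                          channel_means=means.ravel(), info=diagnostics)
    _validate_decomposition(dec, centred)
    return dec


def _validate_decomposition(dec: ICDecomposition, centred: np.ndarray):
    """Algebraic validity checks; raises ICAConvergenceError on failure."""
    ident = dec.unmixing @ dec.mixing  # identity on the retained subspace
    err_id = np.linalg.norm(ident - np.eye(dec.n_components)) \
        / max(1.0, np.linalg.norm(np.eye(dec.n_components)))
    proj = dec.mixing @ dec.unmixing
    recon_err = np.linalg.norm(proj @ centred - dec.rank_reduced_data()) \
        / max(np.linalg.norm(centred), 1e-30)
    if err_id > 1e-6 or recon_err > 1e-6 or not np.isfinite(err_id):
        raise ICAConvergenceError(
            f"invalid decomposition (identity error {err_id:.2e}, "
            f"reconstruction error {recon_err:.2e})",
            dec.info | {"identity_error": float(err_id)})


def _peak_rate_per_min(trace: np.ndarray, fs: float) -> float:
    x = trace if stats.skew(trace) >= 0 else -trace
    mad = stats.median_abs_deviation(x, scale="normal")
    if mad == 0:
        return 0.0
    threshold = np.median(x) + 4.0 * mad
    peaks, _ = find_peaks(x, height=threshold,
                          distance=max(1, int(round(0.2 * fs))))
    minutes = len(x) / fs / 60.0
    return len(peaks) / minutes if minutes > 0 else 0.0


def _spectral_slope(trace: np.ndarray, fs: float) -> float:
    # descriptive feature only; a bounded slice is plenty
    trace = trace[:50000]
    nper = min(len(trace), max(256, int(fs)))
    f, pxx = welch(trace, fs=fs, nperseg=nper)
    keep = (f >= 1.0) & (f <= min(45.0, fs / 2 * 0.9)) & (pxx > 0)
    if keep.sum() < 4:
        return 0.0
    slope = np.polyfit(np.log10(f[keep]), np.log10(pxx[keep]), 1)[0]
    return float(slope)


def component_features(dec: ICDecomposition) -> list[dict]:
    """Per-component map/trace features used by the heuristic classifier."""
    fp_idx = channel_indices(dec.channel_names, FRONTOPOLAR_CHANNELS)
    par = [ch for ch in PARIETAL_CHANNELS if ch in dec.channel_names]
    par_idx = channel_indices(dec.channel_names, par)
    fs = dec.sampling_rate_hz
    feats = []
    for k in range(dec.n_components):
        col = dec.mixing[:, k]
        energy = float(col @ col)
        trace = dec.sources[k]
        feats.append({
            "frontopolar_concentration":
                float(col[fp_idx] @ col[fp_idx]) / energy if energy else 0.0,
            "parietal_concentration":
                float(col[par_idx] @ col[par_idx]) / energy if energy else 0.0,
            "kurtosis": float(stats.kurtosis(trace)),  # excess
            "peak_rate_per_min": _peak_rate_per_min(trace, fs) if fs else 0.0,
            "spectral_slope": _spectral_slope(trace, fs) if fs else 0.0,
        })
    return feats


def classify_components(dec: ICDecomposition,
                        sampling_rate_hz: float | None = None,
                        rules: dict | None = None) -> list[str]:
    """Assign exactly one label per component (stored on ``dec``).

    Blink rule: frontopolar map-energy concentration above threshold AND
    excess kurtosis above threshold AND peak rate within the physiological
    band (defaults 0.5 / 5 / [2, 40] per minute). Parietal-dominant,
    low-kurtosis components are labelled brain; the rest "other".
    """
    if sampling_rate_hz:
        dec.sampling_rate_hz = float(sampling_rate_hz)
    if dec.n_components < 1:
        raise ValueError("decomposition has no components")
    rules = DEFAULT_CLASSIFIER_RULES | (rules or {})
    feats = component_features(dec)
    lo, hi = rules["blink_peak_rate_per_min"]
    labels = []
    for f in feats:
        if (f["frontopolar_concentration"]
                > rules["blink_frontopolar_concentration"]
                and f["kurtosis"] > rules["blink_kurtosis"]
                and lo <= f["peak_rate_per_min"] <= hi):
            labels.append("blink")
        elif (f["parietal_concentration"]
                > rules["brain_parietal_concentration"]
                and f["kurtosis"] < rules["brain_kurtosis"]):
            labels.append("brain")
        else:
            labels.append("other")
    dec.labels = labels
    dec.features = feats
    return labels


def blink_component(dec: ICDecomposition) -> int | None:
    """Index of the most frontopolar-concentrated blink component, if any."""
    if not dec.labels:
        classify_components(dec)
    cand = [k for k, lab in enumerate(dec.labels) if lab == "blink"]
    if not cand:
        return None
    return max(cand,
               key=lambda k: dec.features[k]["frontopolar_concentration"])


def backproject(dec: ICDecomposition, component_subset) -> Recording:
    """Scalp signal carried by a subset of components.

    Summing backprojections over a partition of all components reproduces
    the rank-reduced (centred) data exactly; channel means are not added
    back.
    """
    subset = np.atleast_1d(np.asarray(component_subset, dtype=int))
    if subset.size == 0:
        raise ValueError("component subset must be non-empty")
    if subset.min() < 0 or subset.max() >= dec.n_components:
        raise IndexError(f"component indices out of range "
                         f"(0..{dec.n_components - 1})")
    data = dec.mixing[:, subset] @ dec.sources[subset, :]
    return Recording(data=data, sampling_rate_hz=dec.sampling_rate_hz or 1.0,
                     channel_names=dec.channel_names,
                     subject_id="backprojection", run_id="all")
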