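# Methods

This note documents the models, defaults and numerical choices behind
`blinkerp`, and what the synthetic cohorts do and do not establish.

## Synthetic oddball cohorts

**Protocol.** Each subject performs `n_runs = 3` runs of
`n_stimuli_per_run = 125` visual stimuli, 20 % targets placed uniformly at
random after two leading standards. Stimuli last 200 ms; successive onsets
differ by 200 ms + U(2000, 3000) ms, and each run opens with one
ITI-distributed lead-in and closes with a 2.5 s silent tail so no epoch is
clipped at the run edges. The test-scale sampling rate is 250 Hz
(`sampling_rate_hz`); 1 kHz, the rate of the emulated recordings, is
supported, and every window is specified in milliseconds so nothing depends
on the rate. Onsets are stored in seconds on disk and milliseconds in
memory; analysis windows are half-open `[start, end)` except the
blink-assignment window `(0, 1500]`, which is exclusive on the left.

**Behaviour.** Targets are detected with probability `hit_rate = 0.984`;
response latency is normal, 397.2 ± 38.9 ms, truncated positive. Each
standard/target trial independently receives at most one blink with
probability 0.46/0.48. Blink latency is Gamma-distributed with coefficient
of variation 0.30 — a Gamma was chosen for positive support and the
right-skew of empirical blink-latency histograms; the CV is a modelling
choice, not an empirical fit. Two anchoring presets exist because the
three latency means the emulated study reports (595 ms standards-from-
stimulus, 779 ms targets-from-stimulus, 511 ms targets-from-response) are
not jointly consistent with any single anchoring model plus the 397.2 ms
mean RT: `stimulus_anchored` (default) times target blinks from stimulus
onset with mean 779 ms; `response_anchored` times them from the trial's
own button press with mean 511 ms (targets without a response then blink
with probability 0 — there is nothing to anchor to). Standard-trial blinks
are always stimulus-anchored, mean 595 ms. A drawn blink landing beyond
the next stimulus onset (or violating the 250 ms refractory interval) is
redrawn at most 5 times, then dropped; blink spillover across trials is
never generated. Task-unrelated background blinks are supported
(`background_blink_rate_hz`) but default to 0, keeping truth tables exact;
the real data's out-of-window blink rate is unknown, so this default is a
modelling choice, not an inference.

**Sources.** Four event-locked sources are mixed linearly:

| source | anchor | kernel | peak amplitude (µV) |
| --- | --- | --- | --- |
| p300 | stimulus | Gaussian bump, centre 400 ms, σ 60 ms | 8 standard / 16 target |
| brp | blink | Gaussian bump, centre +300 ms from T0, σ 60 ms | 18 (both classes) |
| motor | response | Gaussian bump, centre +50 ms, σ 50 ms | 8 |
| blink artifact | blink | biphasic pulse: positive lobe σ 55 ms peaking at T0, 0.3× negative rebound at +160 ms | 120 |

Neural scalp maps are computed with the package's own spherical forward
model from fixed dipoles: P300 at (0, −58, 44) mm and BRP at
(0, −62, 36) mm — both inside the toy "precuneus" region, with different
orientations so their maps are distinguishable (|cos| ≈ 0.5) — and the
motor source in the left motor region. The artifact map is a
frontopolar-dominant gain profile (Fp1/Fp2 carry ~85 % of its energy),
mimicking the corneo-retinal dipole; its 120 µV amplitude keeps it ≥ 5×
any neural source at the frontopolar channels. Maps are unit-norm, so
amplitudes are in source units; at the scalp the target P300 peaks at
~15 µV on Pz and the BL-locked BRP at ~5 µV — the upper end of the
physiological range, chosen once so that subject-level ICA isolates the
sources the way it does on real recordings. The class-independence of the
BRP is built in: it is the planted null that comparison 6 must not reject.

**Noise.** Default background is `pink_rms_uv = 5` µV of 1/f noise per
channel plus 1 µV white sensor noise. The 1/f background is *spatially
structured by default* (`spatial_structure = "dipolar"`): 40 random
intracranial dipoles with independent 1/f time courses are projected
through the head model and scaled to the target per-channel RMS.
Channel-wise independent pink noise (`"independent"`) is also available
but is spatially white — unlike any real EEG — and in that regime no ICA
variant can isolate µV-scale evoked sources; the structured default
reproduces the rank structure that makes ICA meaningful. An optional
narrowband (alpha-like) component can be added.

**What passing on this generator does not show.** Sources are exactly
dipolar in an exactly spherical head; maps are identical across subjects;
the artifact is a stereotyped pulse with no saccades, muscle, or line
noise; behaviour is stationary. Recovery here validates the *pipeline's
logic and statistics*, not its robustness to real-world artifact
diversity, inter-subject anatomical variability, or non-stationarity.

## Decomposition

Rank is the number of covariance eigenvalues above 1e−10 × the largest.
ICA is scikit-learn FastICA (non-Gaussianity maximization), seeded, with
`n_components = rank` by default. The unmixing matrix is estimated on a
temporally decimated copy (≤ 20 000 samples; the pipeline stage uses
40 000) and applied at the full rate — the spatial mixture is
time-invariant, so decimation trades only statistical efficiency.
Tolerance is 1e−5 with ≤ 200 iterations: on realistic full-rank data the
fixed-point iteration never "converges" in the strict sense, because the
near-Gaussian background subspace has no identifiable rotation; this does
not affect the identified super-Gaussian components. A decomposition is
therefore validated algebraically — finite weights, `unmixing · mixing ≈ I`
(1e−6 relative), and exact reconstruction of the rank-reduced data — and
failing that raises with the iteration diagnostics attached.

Component labelling is a three-feature heuristic standing in for trained
classifiers: *blink* requires frontopolar map-energy concentration > 0.5
(fraction on Fp1+Fp2), excess kurtosis > 5, and a peak rate of 2–40/min
(median + 4 robust σ threshold, 200 ms refractory); *brain* requires
parietal concentration > 0.5 with excess kurtosis < 5; everything else is
*other*. Thresholds live in `DEFAULT_CLASSIFIER_RULES` and can be
overridden. The MAD in all robust thresholds is normal-consistent
(×1.4826), making "4 MAD" a true 4 σ under Gaussian baseline — with the
raw MAD the threshold sits at ~2.7 σ and noise peaks flood the detector.

## Group clustering

Maps (mixing columns, unit-norm, sign-aligned so the largest-|entry| is
positive) are clustered greedily on absolute cosine similarity with a
seed threshold of 0.7; within a cluster each subject contributes only its
best-matching component. Significance uses a channel-permutation null
(entries of each member's map independently permuted within subject,
999 permutations by default): the cluster false-positive rate is
controlled by testing the mean within-cluster |cos| against the null, and
the member-join false discovery rate by testing each member's |cos| to
the leave-one-out centroid and BH-adjusting across all joins; both at
α = 0.05. P-values use the add-one permutation estimator, so they do not
depend on α and retention is monotone in α. Known limitation: any smooth
(dipolar) topography looks extreme under a channel-permutation null, so
consistent *background* map shapes can form statistically significant
nuisance clusters; they carry non-ROI dipole labels and are removed by the
ROI selection, but users clustering real data should read cluster counts
with this in mind.

## Dipole fitting

The head is three concentric spheres (brain/skull/scalp radii 80/85/92 mm,
conductivities 0.33/0.0041/0.33 S/m, insulating exterior). The scalp
potential is the spherical-harmonic series of the boundary-value problem,
solved per order n (a 4×4 linear system for the shell coefficients;
n ≤ 80, geometric convergence); with equal conductivities it reduces to
the classical single-sphere closed form (2n+1)/n, which is checked in the
tests. Electrode positions come from the standard 10-20 template,
re-projected onto the scalp sphere. Average reference is applied to both
map and forward potentials, so fits are reference-free; residual variance
(1 − explained/total energy, scale-invariant) is the error functional.
Stage 1 evaluates every grey-matter grid point (34×34×17 lattice over
±85 mm, z 0–85 mm, intersected with the toy grey-matter mask) with the
orientation solved by linear least squares; stage 2 refines the position
by Nelder-Mead (orientation still closed-form), constrained inside 98 %
of the brain radius, and never returns a worse fit than the grid minimum.
Labels are the Euclidean-nearest grey-matter voxel; exact ties go to the
lexicographically smallest label and are logged. The label grid is a toy
fixture — seven spherical regions (precuneus at (0, −60, 40) mm, frontal,
motor left/right, occipital, temporal left/right, radius 22 mm) — and
deliberately reproduces none of the anatomical realism of template-based
pipelines.

## Blinks and ERP statistics

Blink peaks: polarity normalized by skewness, threshold median + 4 robust
σ, 200 ms refractory (larger peak wins). First-blink assignment consumes
each blink for at most one stimulus (earlier stimulus wins in the
never-occurring overlap case) and computes latencies from stimulus onset
and, for responded targets, from the trial's own button press. Epochs are
extracted at Pz from the ROI-reconstructed recording; every epoch type is
baselined on the 500 ms preceding its *trial's stimulus onset* (also for
response- and blink-locked epochs, via the trial index), which makes
baseline correction idempotent and keeps mixed-locking comparisons on a
common reference. Grand averages are unweighted means of subject means.

For the six planned comparisons, conditions with different locking are
mapped onto the first condition's axis by the cohort's *measured* mean RT
or mean blink latency (never the nominal values), linearly interpolated
and restricted to the overlap; the paired t-tests then run pointwise over
the post-stimulus (comparisons 1–5) or post-blink (comparison 6) region
with BH-FDR across tested timepoints at α = 0.05. The emulated study
aligned axes this way explicitly only for visualization while testing "all
time points following stimulus administration"; testing on the
shifted-overlap axis is this package's reading (it pairs physiologically
corresponding samples), and `align_before_test=False` provides the
raw-axis alternative. Degenerate pointwise cases are defined explicitly:
identical conditions give t = 0, p = 1; a constant non-zero difference
gives p = 0. Windows of interest are a fixed catalogue (P300 300–500 ms;
response-locked P300 400–600 ms; standard-trial BRP 800–1000 ms = 595 +
300; target-trial BRP 1000–1200 ms = 779 + 300; response BRP 1100–1300 ms
= 397 + 511 + 300; blink-locked BRP 200–400 ms after T0), each reported
as the fraction of its tested timepoints reaching significance.

## Pipeline, seeds, problem sizes

`run_pipeline` derives every seed (per-subject simulation, per-subject
ICA, clustering) from one master seed via `SeedSequence`, making all
outputs byte-reproducible. ICA runs per subject on concatenated runs by
default (`ica_per_run` decomposes runs separately and offers every run's
maps to the clustering). Subjects absent from all ROI clusters contribute
nothing downstream; comparisons require ≥ 3 subjects with all five epoch
types and are skipped (with a warning) otherwise, while
`pointwise_paired_test` itself refuses < 3 subjects.

Problem sizes used by the test suite and the reproduction script are the
package's desk-scale choices: cohorts of 17 subjects × 3 runs at 250 Hz
for the end-to-end checks, extended (same preset, further seeded subjects)
until ≥ 2000 assigned blinks per condition when a latency mean is being
estimated; 100 subject-mean-level replicates for the comparison-6 null
calibration (a full-pipeline replicate per draw would add nothing to what
it tests — the FDR behaviour of the pointwise comparison under the planted
null — at ~100× the cost); ≥ 5000 simulated target trials for the
behavioural statistics.

## Known limitations

- The anatomy (spherical shells, toy label grid) supports method
  validation only; positions and labels are not comparable to
  template-based localization.
- The component classifier is a fixed-threshold heuristic; on real data it
  stands in for trained classifiers plus visual inspection and should be
  re-tuned.
- The channel-permutation clustering null over-rejects for smooth
  topographies (see above).
- Muscle/line-noise/saccade artifacts, inter-subject map variability and
  non-stationary behaviour are not modelled.
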