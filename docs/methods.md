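# Methods

This note documents the models, defaults and numerical choices behind
`heartcouple`, and what the synthetic benchmark does and does not show.

## Signal model of the synthetic generator

Each recording has one time axis shared by four PCG channels (A, P, T, M)
and one ECG channel (E). Per cardiac cycle (default 75 bpm):

- **S1 and S2** are Gaussian-windowed sinusoids (centers 60 Hz and 90 Hz,
  burst width 50 ms, Gaussian σ = width/4). S2 is placed at 35% of the
  cycle (end-systole). Site-specific amplitude pairs (S1, S2) — A (0.7,
  1.0), P (0.6, 0.9), T (1.0, 0.6), M (1.1, 0.5) — mimic the clinical rule
  that S1 is loudest at the apex and S2 at the base; per-site latencies of
  0–6 ms stand in for acoustic propagation.
- **Murmur (abnormal class only)**: band-limited Gaussian noise
  (Butterworth-filtered white noise, default 100–400 Hz, inside the
  4.85–1250 Hz analysis band), gated by a Gaussian systolic envelope. A
  fraction `shared_murmur_fraction` (default 0.8) of the murmur *amplitude
  variance* is one component mixed identically into all four PCG channels;
  the remainder is channel-independent. The shared component is what raises
  PLV, Pearson correlation, cosine similarity and coherence and lowers
  cross-entropies in the abnormal class — the qualitative signature the
  features are designed to detect. Default murmur gain 0.5 relative to the
  unit-scale S1/S2 bursts gives a clearly audible but not dominating
  murmur.
- **ECG**: a PQRST sum of five Gaussians with the R peak 40 ms before S1,
  plus a 0.3 Hz sinusoid and a linear ramp as baseline drift (so wavelet
  detrending has a visible job), plus white noise.
- **Noise**: additive white noise, default SD 0.05, identical for both
  classes.
- **Determinism**: all random components are drawn in a fixed order
  regardless of label, so recordings are bit-reproducible for a seed, and a
  normal/abnormal pair built from the same parameters differs exactly by
  the gated murmur. Cohort recording *i* uses `seed + i`.
- Defaults: 5 s at 4 kHz. Cohort default 30 normal / 30 abnormal — large
  enough for stratified 70/30 splits with the default ReliefF
  neighbourhood (k = 10 needs ≥ 11 training samples per class), small
  enough that a full run stays a desk-scale job.

What the generator does **not** emulate: disease-specific murmur morphology
(ASD/VSD/PDA/TOF signatures), respiration and movement artifacts,
inter-beat variability, sensor coupling differences, or the *sequential*
(non-simultaneous) site recordings of public corpora such as the 2022
heart-sound challenge data. Passing tests therefore demonstrate that the
pipeline recovers inter-channel coupling structure when it exists
simultaneously across channels; they do not certify clinical performance,
and applying the pipeline to sequentially recorded sites would first
require a pairing/synchronization step that is out of scope here.

## Preprocessing

- PCG: zero-phase (forward-backward) Butterworth band-pass, order 4 per
  pass, band 4.85–1250 Hz. Forward-backward application squares the
  magnitude response and cancels phase delay, preserving S1/S2 timing.
  Symmetric (`even`) padding with a pad length of ~3 periods of the low
  band edge; the library default pad length is far too short for a 4.85 Hz
  edge and leaks edge transients (measurably: a 2 kHz stop-band tone at
  20 kHz sampling passes at 6.7% RMS with the default pad, 2.1% with ours,
  against an analytic floor of 1.9%).
- ECG: Daubechies-4 discrete wavelet decomposition, default depth 10, with
  the deepest approximation coefficients zeroed before reconstruction
  (trend removal; perfect-reconstruction means adding the discarded
  component back recovers the input to ~1e-8), then a 5–15 Hz band-pass
  that sharpens the QRS complex. The depth is clamped to the
  boundary-safe maximum for short or resampled records.
- Resampling: default target 2000 Hz (polyphase, anti-aliased), applied
  before filtering. The entropy features are O(N²), and 2000 Hz keeps the
  whole murmur band while making whole-record entropy computation
  tractable; the PCG band's upper edge is clipped to 95% of Nyquist (950 Hz
  at the default rate).
- Normalization: per-channel z-scoring last, so entropy tolerances and
  Euclidean distances measure shape rather than gain.

## Coupling features — definitions and conventions

13 features per unordered pair, computed on the preprocessed, z-scored
channels; entropy features use a centered crop of at most `max_points`
samples (default 2000, i.e. 1 s at the default rate).

- **Cross-sample entropy**: templates of length m from x are compared to
  templates from y; Chebyshev distance, strict `d < r` match. The match
  fraction at length m is `B_i^m = (1/(N−m+1)) Σ_{j≠i} Θ(r−d)` — note the
  self-index is excluded while the template count stays in the
  denominator, so even with every pair matching `B^m = (n−1)/n` and the
  r→∞ limit is a tiny positive constant (~3e-4 at N = 60) rather than
  exactly 0. Tolerance r = 0.2 × the pooled SD of the cropped pair,
  m = 2 (the de-facto standard when unstated). When no template pair
  matches at either length the value is undefined: NaN plus a
  RuntimeWarning, never silently 0.
- **Cross-fuzzy entropy**: same template scheme, each template mean-removed,
  hard threshold replaced by `exp(−d/r)` (a squared/Gaussian kernel
  `exp(−(d/r)²)` is available as a config switch). Normalization is 1/N
  over the valid j≠i pairs. Always finite for r > 0 and continuous in r.
- **Joint distribution entropy**: all Euclidean distances between m-length
  templates of x and of y are pooled and histogrammed into B = 64
  equal-width bins spanning [min d, max d]; the value is the Shannon
  entropy (bits) of the bin probabilities, with no log₂B normalization.
  All-equal distances (one occupied bin) give 0.
- **PLV**: modulus of the mean unit phasor of the instantaneous Hilbert
  phase difference. For independent noise it concentrates near 1/√N.
- **MSC**: Welch coherence (Hann window, default length 1 s, 50% overlap,
  no detrending), summarized as mean and SD over 4.85–1000 Hz. At least two
  segments are required — single-segment coherence is identically 1.
- **CPSD**: the raw windowed-segment average `S_XY = (1/M) Σ X_m Y_m*`
  (no density scaling, no one-sided doubling, no detrending), so a single
  rectangular window reduces exactly to the DFT product `X(f)·Y*(f)`; this
  is why it is implemented directly on `rfft` rather than through a
  spectral-density routine with its own normalization. Summaries: mean and
  SD of the real and imaginary parts over the analysis band.
- **Waveform similarity**: Pearson correlation (mean-removed), cosine
  similarity (no mean removal — deliberately distinct from Pearson), and
  plain Euclidean distance on the z-scored channels.

Pair enumeration is fixed: sites ordered A, P, T, M, E, pairs AP, AT, AM,
AE, PT, PM, PE, TM, TE, ME (E-pairs dropped when the ECG is absent), names
`<PAIR>_<measure>`. Swapping the members of a pair leaves 12 of the 13
features unchanged; only the mean of the imaginary CPSD part negates
(Hermitian symmetry). This order is the on-disk column order, and feature
tables read back from disk are restored to it by name.

## Selection

ReliefF with internal per-feature max-min scaling (weights are therefore
invariant to any prior affine feature scaling), Euclidean neighbour
distances, k = 10 neighbours, full deterministic pass over all samples by
default; miss contributions are prior-weighted per class (the standard
multi-class extension). Constant features get weight exactly 0. Top-fraction
selection sorts descending by weight with ties broken by ascending index;
the kept set size is `max(1, round(fraction·n))`. The default fraction is
0.6, matching the ~60% retention of the reference dimensionalities
(78→48, 130→74); 0.2 is the stricter "top fifth" variant and is a one-line
config change (`selection.fraction: 0.2`). The Mann-Whitney screen uses
exact enumeration for groups of ≤ 8 without ties, otherwise the
tie-corrected normal approximation, and reports Benjamini-Hochberg
q-values.

## Classifier and evaluation

The multiscale CNN treats the selected feature vector as a 1-D sequence
(canonical order, so adjacent entries belong to the same channel pair and
small kernels span within-pair patterns while larger ones cross pair
boundaries). Branches with kernel sizes {1, 3, 5} (each two stacked
same-padded convolutions, 16 filters) are concatenated along channels, then
batch-normalized, rectified and max-pooled (size 2), then a 32-unit dense
layer and a softmax head. Training: cross-entropy, Adam (lr 1e-3), batch
16, 200 epochs, all seeded; a trailing batch of one sample is merged into
the previous batch to keep batch statistics defined. The implementation is
plain numpy with explicit gradients, which keeps runs bit-reproducible.
Kernel sizes, filter counts, pooling and epochs are configurable; the
defaults were chosen for a ~50–130-dimensional input and are not tuned per
dataset.

Evaluation: `n_repeats` (default 20) stratified 70/30 splits with
repeat-derived seeds. Inside each repeat, ReliefF is fitted on the training
fold only, the kept indices are applied to both folds, features are
standardized with training-fold statistics, and the classifier is trained
from scratch. The confusion matrix is summed over repeats; reported
Acc/Pr/Se/Sp/F1 are means of the per-repeat percentages, with zero-denominator
metrics flagged undefined (NaN) rather than zeroed. The per-repeat record
includes the kept feature indices and test indices, which is what the
leakage audit in the test suite checks. Baseline classifiers (logistic
regression, SVM, decision tree, k-NN, Gaussian naive Bayes) are thin
scikit-learn delegates for comparison runs only.

## Problem sizes used by the test suite

The acceptance experiment simulates 30 normal + 30 abnormal recordings of
5 s at 4 kHz, preprocesses to 2 kHz, extracts all 130 features and runs 5
evaluation repeats; on one CPU this is a few minutes, dominated by the
O(N²) entropy features (N = 2000 crop, ~0.5 s per pair). Unit tests use
shorter records (2 s) and smaller entropy crops (300–400 samples), which
changes feature values but none of the contracts under test. Pilot runs of
the acceptance cohort sit comfortably above the 80% mean-accuracy bar
(typically 100% at these defaults); the bar is deliberately conservative
so that it tests the pipeline, not the random seed.

## Known limitations

- Cross-sample entropy can be undefined (NaN) for very short crops or tiny
  tolerances; downstream cohort assembly treats non-finite features as an
  error, so `max_points` and `r` must be chosen generously enough for the
  record length (the defaults are).
- The simulator's synchrony assumption means results do not transfer to
  sequentially recorded auscultation sites without an explicit alignment
  step.
- Batch normalization uses running statistics with momentum 0.1; with very
  few training steps the inference-time statistics are noisy, so extremely
  small `epochs` × `batches` products degrade prediction more than the
  training loss suggests.
- The Fourier-domain features assume stationarity over the window length
  (1 s default); strongly arrhythmic signals would violate this.
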