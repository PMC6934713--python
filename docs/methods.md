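# Methods

This note documents the models, conventions and numerical choices behind
`swaylearn`, in the order data flow through the pipeline. Everything stated
here is either a definition or a design choice; empirical claims about
behaviour are made only where the test suite or `scripts/acceptance.py`
computes them.

## Synthetic cohort model

The simulator generates the kind of data the analysis assumes rather than a
biomechanical reconstruction of balancing bodies. Each participant carries a
latent motor-atypicality severity s ≥ 0 drawn from a group-specific Gamma
distribution (defaults: ASD mean 1.0 / shape 4, TD mean 0.3 / shape 2, so TD
severity is stochastically smaller). Clinical covariates are monotone
functions of s plus Gaussian noise: the standardized motor percentile
(BOT-2-like, clamped to [1, 99]) decreases in s; the two symptom scales
(SRS-2-like, RBS-R-like) increase in s. IQ and sex are drawn from
group-specific distributions matched to the cohort shape the defaults
emulate (39 ASD / 23 TD, ages 7–18) and are independent of s, so they should
*not* predict the classifier output — a negative control.

Each channel of a recording is the sum of three components:

* **drift** — a mixture of 3 sinusoids with frequencies drawn uniformly
  from [0.05, 0.5] Hz and amplitudes from [0, 3] (arbitrary position
  units): the slow postural signal itself;
* **AR(1) noise** — coefficient φ = 0.95 at the nominal 30 Hz frame rate,
  scaled to a stationary SD of
  σ = σ_base · (1 + β·s·1[channel affected]) · a(age, group);
* **jitter** — i.i.d. Gaussian noise (SD 1.0), the high-frequency sensor
  artifact the wavelet stage exists to remove.

The *affected* channel set defaults to head, both shoulders, both feet
(all three axes) and the two board channels — the body regions the
analysis is expected to highlight. β (default 2) converts severity into
noise-SD inflation: an affected channel of an s = 1 participant has 3× the
noise SD of an unaffected one. The age factor
a = max(0.2, 1 + 0.10 · (13 − age_eff)) decreases ~10 %/year around the
cohort-mean age of 13, and age_eff subtracts a 3-year developmental delay
for the ASD group, so a young TD participant resembles an older ASD
participant — this is what lets the pipeline reproduce, qualitatively, the
negative age–boundary-distance correlation and the "younger TD
misclassified toward ASD" pattern. The slope 0.10/yr was fixed during
generator calibration as the smallest value in the candidate set that made
the age-correlation sign stable across seeds; it is a modelling choice, not
a fitted quantity.

Artifacts: cells go missing independently with p = 10⁻⁵ (missingness is
rare in the motivating data); with probability 0.05 a whole file is
corrupted by scaling each channel's deviations from its mean by √10⁴, which
multiplies every variance by exactly 10⁴ — the malfunction signature the
variance QC must catch.

Reproducibility: the cohort is drawn from `rng_seed`; each recording (and
its corruption draw) from a SHA-256 hash of (seed, participant, session,
pose), so any single file regenerates byte-identically in isolation.

**What the simulator does not emulate:** skeletal geometry or joint
coupling, the shapes of the 10 poses, non-stationarity within a session,
learning across sessions, and any distributional detail of the real
instruments beyond monotone severity links. Passing calibration on this
cohort therefore shows that the pipeline recovers variance/entropy-coded
group structure from noisy multichannel timeseries — not that it would
reach any particular accuracy on real recordings.

**Problem sizes.** Recordings default to 960–1920 raw frames (30–60
decimated samples, i.e. 2–5 feature windows each), and the calibration runs
use 20 + 20 participants × 3 sessions × 10 poses = 1,200 files per seed.
These sizes were chosen so that the full multi-seed calibration suite runs
comfortably at a desk while preserving the structure of the full-scale
setting (sessions 2–4 of a 62-participant cohort, ~1,860 files, up to
10,000 frames per file).

## Cleaning

* **Imputation** — last valid value carried forward. Leading missing values
  are back-filled from the first valid value (the forward rule has nothing
  to propagate there); an all-missing channel is an error. Idempotent.
* **Haar denoising** — the series is replaced by its level-L (default 5)
  approximation coefficients, *decimated* (length ≈ T/2⁵), not a
  full-length reconstruction: the downstream window of 20 samples is
  defined on this coarse series, which only makes sense on a decimated
  signal. Coefficients are rescaled by 2^(−L/2) so they equal dyadic block
  means — a constant series maps to itself and denoising commutes with
  adding a constant. Boundary rule: symmetric (half-sample) padding, output
  length ⌈T/2⌉ per level. If T < 2^L the level drops to ⌊log₂T⌋ with a
  warning. The effective frame rate becomes frame_rate/2^L.
* **Trimming** — centred window of at most N samples (default 10,000),
  start index ⌊(T−N)/2⌋; shorter series pass through. Applied after
  decimation by default (the stage order puts denoising first); a config
  flag moves it before.
* **Variance QC** — per pose and channel, the per-file population variances
  are modelled as exponential; the ML rate is 1/mean, so the upper-q
  quantile (q = 10⁻⁷) is mean · ln(1/q) ≈ 16.12 · mean. A file is discarded
  iff any channel's variance exceeds its threshold. The fit uses *all*
  files of the pose in a single pass — no leave-one-out, no re-fit after
  discarding — which is the simplest reading of the procedure. A
  consequence worth knowing: with n files per pose, a single dominating
  outlier inflates the mean by ~x/n and is only discardable when
  n > ln(1/q) ≈ 16.1; at realistic pose sizes (≥ ~40 files) this is
  immaterial, and corrupted files (10⁴× variance) clear the threshold
  easily. Poses with fewer than two files skip QC with a warning.

Variance is population variance (divide by n) throughout cleaning and
features, for consistency.

## Features

Windows of W = 20 samples shifted by S = 10; windows that would cross the
series end are dropped, so a recording of T decimated samples yields
⌊(T−W)/S⌋ + 1 vectors (0 if T < W, with a warning). Per window and channel:

* **entropy** — Shannon entropy of the histogram over B = 10 equal-width
  bins spanning the window's own [min, max]; 0·log 0 := 0; zero-range
  windows have entropy 0; natural log by default (`bit` available). Binning
  on the window's own range makes the estimator shift- and scale-invariant:
  it measures the *shape* of the value distribution, not its spread. The
  estimator itself was an open choice; a histogram estimator was picked for
  transparency and because B and the base are exposed in config.
* **variance** — population variance of the window.

Feature order is entropies of all channels, then variances, in schema
order; names like `entropy:shoulder_R:y` and `variance:board:x` are the
public vocabulary of every importance and effect-size report.

## Classifier

Per-pose random forests: 10 trees, Gini splitting, bootstrap resampling,
minimum leaf size 5, √(n_features) candidate features per split, unbounded
depth. The tree-training parameters of the original analysis are not
available, so these are standard random-forest defaults; all are exposed in
`ForestParams` and recorded in model metadata. Each pose's forest gets a
seed derived from the ensemble seed, making training deterministic.

Voting: a window vector votes ASD iff its forest score (mean leaf ASD
fraction over trees) is ≥ 0.5; the pose decision is the majority of vector
votes; the participant label the majority of pose decisions. Ties break
toward ASD at both levels — an explicit, testable rule chosen because the
motivating analysis shows a strong positive-class (recall 1.00) bias.
Poses with no surviving vectors (e.g. all files QC-discarded) are omitted
from both the vote and the probability.

Continuous output: p = unweighted mean over available poses of the mean
vector score; boundary distance = 2p − 1. Whether the original continuous
measure was score-based or vote-based is not stated; the vote fraction is
therefore computed and reported alongside (`asd_vote_fraction`), and the
score-based p is the primary definition.

## Evaluation

Folds are stratified at the participant level (class counts per fold within
one of proportionality); a participant's windows never appear on both sides
of a split, which the tests audit explicitly. Metrics use the standard
binary definitions with ASD positive; any 0/0 (including a zero MCC
denominator) is reported as 0 and logged. These definitions reproduce every
published worked-example cell exactly from its confusion counts, which is
the evidence they are the intended ones. Fold averages are unweighted
means, matching the published average row.

Differential experiments: `project_xy` removes the 20 joint z-channels
(depth is the least reliable axis of a single markerless camera), leaving
42 channels → 84 features; `balance_groups` keeps the smaller group intact
and subsamples the larger to n per group, seeded.

## Interpretation

* **MDI** — within each forest, scikit-learn's impurity importances are
  (re)normalized to sum to 1; a feature's total is the sum across pose
  forests, so totals lie in [0, n_poses]. This normalization basis matches
  the scale of the published top-20 scores (0.55–0.89 on 10 forests). Ties
  break by canonical feature-name order.
* **Fold consistency** — mean over folds of the overlap |A∩B|/k between the
  fold model's top-k list and the full-data model's top-k list (k = 20).
* **Cohen's d** — computed on per-participant feature means (windows pooled
  across a participant's files first) to avoid pseudo-replication from
  correlated windows; (n−1)-weighted pooled SD; positive sign = ASD > TD;
  zero pooled SD → undefined (NaN). Whether the original distributions
  pooled windows or participants is unstated; participant-level is the
  conservative choice.
* **Correlations** — Pearson and Spearman of boundary distance against each
  covariate, pairwise-complete (participants missing a covariate are
  dropped and n is reported, mirroring symptom scales absent for early
  control participants); constant inputs reported as NaN.

## Known limitations

* The synthetic effect sizes are calibrated only to make the qualitative
  phenomena recoverable (group separation, sign patterns, small-to-large
  per-feature d); they are not fitted to any published magnitudes, and no
  numeric agreement with the original cohort's metric values should be
  expected or is claimed.
* The level-5/30 Hz/window-20 combination implies a window span of ~21 s;
  published remarks about a ~10 s window cannot be reconciled exactly with
  any single frame-rate assumption, so the window is defined in samples and
  both the level and the rate are config-exposed.
* Whether the 10,000-sample cap counts raw or decimated frames is
  ambiguous in the motivating description; the default counts decimated
  samples (trim after denoising, matching the stated stage order) and a
  config flag flips it.
* Probabilities are raw forest scores, not calibrated; the boundary
  distance is a ranking device, not a calibrated risk.
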