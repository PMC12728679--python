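# Methods

## Scope and model

`respifuse` implements a three-modality screening pipeline: fiber-optic
respiratory vibration, respiratory audio, and routine blood indicators,
fused at the feature level and classified by a stacking ensemble. The
package is organized stage-wise (cohort → preprocess → fiber/audio
features → select → fusion → classify → metrics), with the fitted
components (SparseCCA, LowRankFusion, SVSClassifier) exposing
sklearn-style `fit`/`transform`/`predict` interfaces.

## Synthetic cohorts

`generate_cohort` emulates the clinical cohort the pipeline targets:
360 subjects, 282 cancer : 78 non-cancer (3.6:1), with demographics drawn
from class-conditional normals (ages 60.0 ± 11.7 vs 48.3 ± 18.7 years)
and Bernoulli sexes (69.9% vs 52.6% male) matched to the emulated
recruitment moments; demographics feed `cohort_summary` only, never the
classifier.

Per subject the generator draws a shared latent u ~ N(0,1) and produces:

* **fiber** (default 1 kHz): a respiratory fundamental f₀ = 0.25 +
  0.04·u + 0.03·effect·label Hz (clipped to 0.15–0.45), two harmonics at
  relative amplitudes 0.5/0.25, Brownian phase wander whose scale is
  0.05·(1 + 0.8·effect·label) (irregular breathing), white noise
  (σ = 0.1), and Poisson motion spikes (0.2/s, exponential decay).
* **audio** (default 8 kHz): 200–2000 Hz band-limited noise amplitude-
  modulated by inhale/exhale bursts of the same phase process, with
  silence gaps, plus a small sensor-noise floor.
* **depth effect**: the respiratory component of both modalities is
  scaled by exp(0.15·u − 0.20·effect·label + N(0, 0.1)) — positives
  breathe more shallowly and more quietly, and the shared latent couples
  fiber vibration depth with audio loudness (alongside the rate
  coupling), which is the cross-modal structure sparse CCA exploits.
* **blood**: 56 indicators, unit-variance noise; the seven designated
  leukocyte indicators shift by 0.62·effect SD for positives.

Rates default to desk-scale values (fiber 1 kHz, audio 8 kHz) rather than
the acquisition hardware's; readers accept any rate. The effect
magnitudes were calibrated once so that each representative block alone
separates the classes at roughly AUC 0.84–0.88 under cross-validated SVS
classification — the block-level separability of the cohort being
emulated — and were then frozen.

What the generator does **not** emulate: real physiological acoustics
(formant structure of breath sounds, adventitious sounds like crackles or
wheezes), age/sex confounding, inter-indicator correlation in the blood
panel, or co-morbid lung disease. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that its comparative
behaviour holds under the planted statistical structure — not that the
clinical effect sizes or the clinical ranking of fusion methods transfer
to real cohorts.

## Preprocessing

DCT denoising uses the orthonormal type-II DCT, so coefficient truncation
is an orthogonal projection (energy non-increasing, idempotent). The
published acquisition protocol's "coefficient threshold" is interpreted
as an **index** cutoff — energy concentrates at low index and the printed
number is implausible as an amplitude — scaled proportionally to the
sampling rate as a frequency cutoff (default 25 Hz,
`DctDenoiseConfig.from_cutoff_hz`); a magnitude-threshold mode is also
provided. Endpoint detection is the classic three-state double-threshold
machine on 25 ms/10 ms frames; by default thresholds are relative
(ste_high = 0.1 and ste_low = 0.02 of the maximum frame STE, ZCR
threshold = 1.5× the silence-median ZCR, minimum segment 5 frames), which
makes segmentation invariant to amplitude scaling. A final segment that
reaches the last analysis frame is extended to the signal end so a
fully active signal maps to one full-span segment. Optional decimation
after denoising exists but is off by default.

## Feature inventories

Fiber (79): 12 time statistics; 13 statistics on each of Fourier
magnitude, power spectrum and real cepstrum; variance/kurtosis/skewness/
relative energy on wavelet bands D1–D6 + A6 (db4 — the conventional
choice for physiological vibration; 6 levels per the D1–D6 band naming).
Conventions: peak factor = max|x|/RMS, impulse = max|x|/mean|x|, margin =
max|x|/(mean√|x|)², RMS (shape) factor = RMS/mean|x|, spectral SNR =
peak/median magnitude (the source never defines its spectral SNR; this
definition is scale-free and robust), centroid/entropy on normalized
magnitudes. Zero-variance moments are reported as 0 so downstream
selection never sees non-finite values.

Audio (523 = 273 + 130 + 120): stream × functional products. The
frequency block is 39 MFCC streams (13 static + Δ + ΔΔ, 26-mel filterbank,
pre-emphasis 0.97) × 7 functionals; quality is 13 streams (F1–F3, B1–B3
from a batched-Levinson LPC of order 2 + rate/1000 with roots via batched
companion eigenvalues; first differences of F1/F2/B1/B2; second
differences of F1/B1; per-frame jitter |ΔF0|/F0) × 10 functionals;
prosody is 12 streams (F0 by autocorrelation peak with parabolic
interpolation, log-energy, ZCR, STE, SPL, with Δ/ΔΔ variants) × 10
functionals. The published quality-stream enumeration and its printed
feature names disagree; the registry follows the names (which require
second differences of the first formant pair). Names concatenate stream
and functional (`SPLmean`, `mfcc19mean`, `B1sk`), hyphen-joined for
difference streams (`ZCR-de-range`, `F1-de2-sk`). Which functionals
produce the 130/120 block totals is a reconstruction chosen to satisfy
the printed totals while covering every printed exemplar name.

The blood schema documents (in `respifuse.blood`) the reconciliation of
an internally inconsistent printed 56-indicator panel: the duplicated
eosinophil pair is replaced by basophil ratio/count and "total protein"
completes the panel to 56.

## Selection

Contribution = equal-weight mean of three min-max normalized components:
|point-biserial correlation|, impurity importance from a 200-tree seeded
random forest (rows and columns are canonically sorted before the fit so
the score is exactly permutation-invariant), and the two-sample KS
statistic (binning-free "distribution divergence"). Weights are
configurable. Ties break by name order. The violin-plot style screen is
a per-feature Mann-Whitney U with Benjamini–Hochberg correction at 0.05,
reported as a table and not used to gate selection. By default top-20
selection runs inside the training split of any cross-validation
(`--global-selection` reproduces whole-cohort ranking, at a leakage
risk).

## Fusion

Sparse CCA solves the L1-penalized correlation objective by alternating
ridge-stabilized (1e-8) penalized regressions with soft-thresholding and
renormalization, initialized at the leading singular directions of the
cross-covariance, tolerance 1e-6, max 500 iterations; components by
deflation of the fitted variates; λ = 0 reduces to power iteration on the
whitened problem and reproduces classical CCA to 1e-6. Penalties default
to a 5-fold CV grid (0–0.3) maximizing first-component validation
correlation. n_components defaults to 2, so CFLC has width 4. A penalty
large enough to zero a direction raises an explicit error naming it.

LMF trains rank-r factor stacks (default r = 4, h_dim = 8) on a logistic
proxy loss by 2000 full-batch gradient steps at rate 0.01, seeded
initialization scaled by 1/√r, then freezes the factors as a feature
map; training is separate from the downstream ensemble (the alternative,
joint end-to-end training, is not what a frozen-feature pipeline needs
and would entangle the fusion with one classifier). At full rank an SVD
factorization reproduces explicit tensor fusion exactly
(`LowRankFusion.from_tensor`), which is the oracle used in testing; TFN
is test-only, not a user-facing method.

## Classification and evaluation

SMOTE interpolates minority rows toward one of k = 5 minority nearest
neighbors until classes balance, applied strictly inside training splits.
Each base learner (SVM with sigmoid-calibrated probabilities, XGBoost,
KNN, logistic regression, random forest) is grid-searched by inner
3-fold stratified CV (grids ≤ 24 combinations; a `fast` preset collapses
grids to defaults for replicate benchmarks); decision weights are
proportional to inner-CV accuracy and scale the out-of-fold base
probabilities that train the logistic meta-learner — the resolution of
"voting" plus "stacking" coexisting in one ensemble. The operating
threshold is the Youden optimum of the out-of-fold training scores.
Pooled out-of-fold metrics are the default report; per-fold reports are
also returned. The Bayesian tuner slot exists behind the same interface;
grid search is the built-in strategy.

AUC is always the full-curve trapezoid over all score thresholds (a
"single-threshold AUC" is not well defined); the Youden point is reported
prominently as the operating threshold, ties resolved toward higher
sensitivity. MCC returns 0 when any denominator factor vanishes.

## Benchmark problem sizes

The replicate benchmark (`respifuse.benchmark.fusion_benchmark`) runs 20
cohorts of 360 subjects (282:78) end to end from raw signals, with 6 s
recordings at the synthetic rates and a prosody-only audio registry,
since the audio-rhythm representatives are all prosody HSFs; the full 79-
and 523-dimension inventories are exercised on separate cohorts in the
unit suite. Fusion methods are compared by pooled 5-fold CV AUC with all
label-using steps (SCCA penalty selection, LMF training, SMOTE, tuning)
inside each training fold; the SVS-vs-single-learner comparison shares
folds and per-fold features. These sizes are the package's default
benchmark conditions.

## Known limitations

On these synthetic cohorts the CONCAT early-fusion baseline is a strong
competitor to SCCA-LMF and typically wins: the representative blocks are
low-dimensional (9 + 9 + 7) and individually informative, so a tree
ensemble on the raw concatenation is close to optimal and any fixed-width
canonical/low-rank compression can discard class signal that lies outside
the leading cross-modal directions (per-modality irregularity features,
in particular). A clinical advantage for correlation-guided fusion — as
reported on real cohorts — would have to come from structure this
generator deliberately does not plant, such as heavy modality-specific
artifact contamination or label-relevant cross-modal interactions. The
benchmark therefore validates the machinery and the honest comparison
protocol, not a universal ranking of fusion methods. Other limitations:
the LMF proxy loss can overfit small cohorts (no weight decay by
default); formant features on breath-like noise are weakly identified;
the audio functional assignment reconstructs printed totals rather than a
published itemization.
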