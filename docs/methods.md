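# Methods

## Problem and pipeline

`lasap` classifies binary psychosocial-stress status (high vs low caregiver
burden) from two feature blocks extracted from the same interview speech:

* a **linguistic block** — frequency counts of screened keywords in the
  participant's transcript;
* an **acoustic block** — a high-dimensional table of functional statistics
  of low-level descriptors (LLDs), either imported from an external
  ComParE-style extractor or produced by the built-in shimmer extractor.

Because both blocks are extracted from the same recording they are
naturally correlated; fusing them without removing the shared variation
overemphasizes redundant directions and invites overfitting at small
sample sizes.  The pipeline therefore **residualizes (orthogonalizes)**
the acoustic block on the linguistic block before fusion, and quantifies
the value of that step with repeated-seed paired bootstrap confidence
intervals.

Stage order inside every training fold: keyword screening → PCA on the
screened counts → least-squares residualization of the acoustic columns on
the linguistic PCA scores → column-wise fusion → per-column
standardization → classifier.

## Labeling

Stress status comes from the Caregiver Burden Inventory (CBI): 24 items
scored 0–4, total range 0–96.  Totals of 36 or lower are low stress
(label 0); totals above 36 are high stress (label 1).  The positive class
is high stress everywhere.

## Linguistic features

* **Tokenization** is pluggable; the default lowercases and splits on
  whitespace.  Multi-word lexicon phrases are matched greedily longest
  first and consume their tokens, so a phrase hit never double-counts its
  words.  The arithmetic downstream needs only counts, so the tokenizer
  carries no language-specific logic.
* **Screening** keeps a term iff its corpus-wide count is ≥ 2 *and* it
  belongs to the keyword→topic lexicon.  Scope defaults to the training
  fold of each split (`screen="fold"`), consistent with confining all
  preprocessing to training data; `screen="fixed"` supports screening the
  whole corpus once upstream.  Counts are used raw — no tf-idf and no
  document-length normalization — matching the keyword-frequency feature
  definition.
* **PCA** removes redundancy among the screened counts.  The number of
  retained components is the smallest count whose cumulative explained
  variance reaches `variance_fraction` (default 0.95 — a conventional
  choice; no component count is prescribed by the design).  Fitting uses
  training rows only; held-out rows are centered with training means and
  projected with training components.

## Acoustic features

The built-in extractor demonstrates the LLD→functional mechanism
end-to-end:

* **Peak detection**: local maxima with a prominence floor of 5% of the
  signal's amplitude range (configurable); a flat signal has no peaks.
* **Shimmer** (local): `|a(k+1) − a(k)| / ((a(k+1) + a(k)) / 2)` over
  consecutive peak amplitudes — relative consecutive-peak variation
  normalized by the pair mean, which makes the series invariant to
  overall gain.  Shimmer is undefined with fewer than two peaks.
* **Functionals** map any LLD series to a fixed-order 13-vector:
  mean of the 5-point moving average; mean and SD of first differences;
  IQR; minimum positive value; mean and SD of inter-peak distances (the
  SD doubling as the segment-length SD under the inter-peak-segment
  interpretation); mean peak relative height ((peak − min) / range);
  flatness (geometric/arithmetic mean ratio of magnitudes, ε-guarded);
  rise time (fractional position of the maximum); skewness; centroid
  (magnitude-weighted mean fractional position); left center time (the
  same restricted to positions at or left of the maximum).  All SDs are
  population (ddof = 0) SDs; quantiles interpolate linearly between order
  statistics; undefined statistics on degenerate input (skewness of a
  constant series, peak statistics with < 2 peaks) return 0 by convention
  and are logged.

The full 6503-feature ComParE set is imported through the CSV adapter
(`load_acoustic_table`), never re-implemented; rows are realigned by
participant id and missing ids raise.

## Orthogonalization

Let `L` be the centered training linguistic matrix (PCA scores by
default) and `A` the centered training acoustic matrix.  The fitted map
is the least-squares coefficient matrix `C = L⁺ A` computed with a
rank-tolerant pseudo-inverse (singular values below `1e-10 ×` the largest
are dropped — with a wide basis on few training rows the normal equations
can be near-singular).  Application returns `A − L C`: the component of
each acoustic column orthogonal to the linguistic column space.

Properties guaranteed on the training pair (and tested): every residual
column has zero inner product with every centered linguistic column
(≤ 1e-8); residualizing the residual is a no-op (projection idempotence);
column norms never grow.  Held-out rows are transformed with the
training-fitted coefficients — no refit, so exact orthogonality is *not*
asserted out of fold; refitting on test rows would leak their covariate
structure.

Open design choices resolved here: the residualization basis is the PCA
scores (well-conditioned; PCA precedes fusion in the pipeline), with
`ortho_basis="raw"` available for comparison; both blocks are centered
with training means (decorrelation means zero correlation only around the
mean); the design matrix is standardized per column with training
mean/SD after residualization (margin-based classifiers are
scale-sensitive and the acoustic block otherwise dominates by dimension).

## Evaluation

* **Nested (double) CV**: stratified 10-fold outer loop for
  generalization, stratified 5-fold inner loop on each outer-training set
  for hyperparameter selection by mean ROC-AUC.  Preprocessing is refit
  inside every split — inner folds included — so no selection step sees
  its own validation rows.  Stratification is on by default: with a
  44/56 class balance at n = 100, unstratified 10-folds are occasionally
  single-class.
* **Classifier grid**: linear, polynomial, RBF and sigmoid SVMs
  (C ∈ {0.01, 0.1, 1, 10}), k-NN, random forest, extra trees, AdaBoost.
  Ties in inner-CV ROC-AUC go to the earliest grid entry; grids are
  ordered least complex first (strongest regularization, fewest
  neighbors).  ROC-AUC is computed from continuous decision scores
  (`decision_function`, else positive-class probability), never from hard
  labels.
* **Metrics** (all percent): F1 = 2TP/(2TP+FP+FN); accuracy =
  (TP+TN)/total; ROC-AUC = P(random positive outscores random negative),
  ties half; TPR/FPR/FNR/TNR with their complement identities.  A fold
  with no positives predicted *and* none present has undefined F1,
  reported as NaN and excluded from means with a logged count — silent
  zeros would bias exactly the comparison the tool exists to make.
  Per-run aggregation is mean (population SD) over outer folds; fold
  sizes are equal, and population-SD aggregation reproduces the expected
  fold-SD arithmetic exactly under degenerate (single-class) prediction.
  A fold that predicts a single class is flagged in the report.
* **Repeated evaluation**: the whole nested CV is rerun under
  `n_repeats` seeds (base seed + repeat index); the summary is the mean
  and SD over per-repeat means.
* **Paired bootstrap**: per-seed differences (with-orthogonalization −
  without), computed on identical fold assignments because the settings
  share seeds; the CI is the 2.5th/97.5th percentile of those differences
  (linear interpolation between order statistics).  Improvement is
  "established" when the lower bound exceeds 0.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
without any audio:

* latent stress `z ~ N(Φ⁻¹(prevalence), 1)` mapped to an integer CBI total
  `clip(round(36.5 + 12 z), 0, 96)` and thresholded; default prevalence
  0.56 matches a 44/56 low/high balance, and prevalence 0.5 centers the
  latent score at the threshold;
* keyword counts are Poisson with per-keyword base rates (0.5–5 expected
  occurrences) and class-shifted log-rates along a unit-norm loading;
  `ling_effect` (default 1.0) scales the shift;
* acoustic rows are `√c · shared + (δ/2) s v + √(1−c) · σ ε` with
  `c = cross_loading` (default 0.8, the redundancy-heavy regime),
  `shared` a standardized linear map `W` of the standardized counts, `v`
  a unit direction orthogonal to `W`'s row space, and
  `δ = acou_effect · √(1−c) · σ` planting a class shift of `acou_effect`
  (default 0.8) residual SDs along `v`.

Two structural choices make the orthogonalization contrast a testable
property rather than an accident: the map `W` is projected off the
population discriminative direction of the keyword block, so the shared
component replicates linguistic *nuisance* variation — overlapping
redundant information with no predictive value of its own — and the
acoustic-only signal direction `v` is orthogonal to `W`'s row space, so
residualization provably preserves it.  In this regime raw fusion buries
both signals under hundreds of correlated nuisance columns while
orthogonalized fusion removes them, reproducing the qualitative ordering
(fused+orthogonalized > fused raw, > acoustic alone) and a positive
bootstrap lower bound.

What the generator does **not** emulate: real transcripts or any language
structure (counts are exchangeable given the rates), demographic
covariates (none are specified for the study population), temporal or
spectral structure of real speech beyond the toy shimmer waveforms, and
heavy-tailed or missing acoustic features.  Passing tests therefore
demonstrate the pipeline's statistical mechanics — leakage-free fold
logic, exact orthogonalization, calibrated chance level, and the
direction of the orthogonalization benefit under engineered redundancy —
not field performance on recorded speech.

The waveform generator concatenates sine cycles with per-cycle amplitudes
`base · (1 + level · u)`, `u ~ N(0,1)` truncated at ±3 and floored at 5%
of the base amplitude, so the relative peak dispersion is ≈ `level` and
level 0 gives exactly constant peaks.

## Problem sizes and numerical conventions

Acceptance-level checks and the reproduction script run at desk scale:
100 participants, 53 keywords over 14 topics, 300 acoustic features,
10×5 nested CV repeated over 20 seeds — sizes chosen so a complete
comparison runs in minutes on one core while keeping the outer-fold
geometry (10 test rows per fold, 44/56 balance) of the full design.  The
`SyntheticConfig` default of 6503 acoustic features mirrors the full
ComParE dimensionality and is practical for generation, though repeated
CV at that width is correspondingly slower.

Conventions used throughout: population (ddof = 0) SDs for fold and
functional statistics; linear-interpolation percentiles; pseudo-inverse
cutoff 1e-10 relative; positive class = high stress; every random draw
flows from an explicit integer seed (cohorts and fold assignments are
byte-reproducible).

## Known limitations

* The built-in extractor computes one LLD (shimmer); the full LLD set is
  deliberately out of scope and enters only through the import adapter.
* Keyword screening inside folds can select slightly different keyword
  sets per fold; this is the leakage-safe reading and is reported in the
  per-fold artifacts rather than hidden.
* With `cross_loading = 1` the generator has no acoustic-only noise and
  the planted acoustic signal amplitude is 0 by construction (degenerate,
  documented).
* F1 exclusion of undefined folds means F1 means can rest on fewer folds
  than accuracy means; the excluded count is logged.
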