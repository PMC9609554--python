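# Methods

`metaboselect` implements a complete desk-scale analysis chain for
untargeted LC-MS peak tables: QC-based pre-treatment, semi-supervised
metabolome-based sample classification, and nested bootstrap/cross-validated
marker selection. This note records the models, the tunable parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## The data model

A `PeakTable` is an injections × features matrix of chromatographic peak
areas (arbitrary units) with aligned sample metadata (role: study / pooled
QC / blank; cultivar; biological and technical replicate; batch; global
injection order) and feature metadata (m/z in Thomson, retention time in
minutes, ionization polarity). Missing values are a dedicated marker (NaN),
never zero: downstream stages impute rather than zero-fill. Positive- and
negative-mode acquisitions of the same injection sequence live in two
tables sharing sample ids and are column-bound at the end of pre-treatment,
with feature ids namespaced `pos_` / `neg_` so uniqueness holds.

## Synthetic studies

The generator (`synthetic_data`) emulates the study design the analysis
assumes: a panel of 18 cultivars × 3 biological × 2 technical replicates
(108 study injections per polarity) acquired in 9 batches, each batch
bracketed by blanks and threaded with 5 pooled-QC injections (3 blanks per
batch), injections randomized so that both technical replicates of a
prepared extract stay within one batch. The intensity model works on the
log2 scale:

    log2 I = base_f + cultivar_f,c + marker shift ± effect/2 + noise

* `base_log_mean = 17`, `base_log_sd = 2` (log2 of a typical peak area of
  ~1e5 counts with a 4-decade dynamic range);
* `cultivar_log_sd = 0.5` — between-cultivar biological variation. This
  field is what makes pooled QC rows *less* variable than study rows, as
  they must be for the RSD filter to be meaningful;
* `noise_log_sd = 0.2` — within-replicate multiplicative noise
  (≈15% CV, typical of ESI-MS peak areas);
* planted markers: a ± effect/2 shift per latent cultivar group (group 1
  up), default 62 markers at 1.0 log2 across ~3000 features over two
  polarities, allocated proportionally to table size;
* drift: a per-feature exponential trend in within-batch injection
  position, relative amplitude `drift_amplitude = 0.3` per batch with
  lognormal per-feature jitter and random direction, times a per-batch
  multiplicative offset (`batch_offset_sd = 0.1`) shared across features;
* QC rows are the arithmetic mean of the study-sample pre-noise
  intensities (ideal pooling) pushed through the same drift, batch and
  noise nuisances; blanks sit 2^-10 (~0.1%) below the study signal;
* missingness is intensity-censored: a cell goes missing with probability
  ∝ exp(−censor_strength · z) of its standardized log intensity, rescaled
  to an overall `missing_rate = 0.05`.

The latent two-group split defaults to the packaged cultivar panel's
metabolome-group column (an 8/10 split); outside that panel, cultivars
alternate between groups. The generator is fully seeded: the same
configuration reproduces its output bit for bit.

What the generator does **not** emulate: correlated co-eluting features
(adduct/isotope blocks share no structure beyond retention time), retention
time drift, heteroscedastic detector saturation, and batch-specific
missingness. Passing the recovery benchmark therefore shows the selector
behaves correctly under the assumed nuisance structure, not that it is
robust to every pathology of real acquisitions.

## Pre-treatment

Stage order is fixed — impute → QC drift correction → RSD filter →
technical averaging → autoscale → polarity binding — and each stage's
output satisfies the next stage's preconditions.

**Imputation** follows the iterative random-forest (missForest) scheme:
missing cells start at the feature mean; features are swept in order of
increasing missingness, each incomplete feature regressed on all others by
a random-forest ensemble (100 trees, √p candidate features per split) and
its holes replaced by predictions; sweeps stop at the first increase of the
normalized squared difference between successive imputations (the sweep
before the increase is kept) or at `max_iter = 10`. Observed cells are
never modified; a fully missing feature is an error, not a guess.

**QC-based drift correction**: per feature, a gradient-boosted
regression-tree model (100 trees, depth 2, learning rate 0.1; pluggable)
is trained on the pooled-QC injections only, covariates injection order and
batch, and predicts the expected QC-level intensity of every injection.
Each cell becomes

    S_corrected = S_observed / S_predicted × 1000,

so a perfectly predicted cell maps to the constant 1000 and drift common
to QC and study samples divides out. Predictions are floored at 1e-6 of
the feature's QC mean to keep the ratio finite. The tree ensemble with
mean initialization and mean-residual leaves is exactly scale-equivariant:
scaling a feature's column by k > 0 leaves its corrected values unchanged.
Only injection covariates enter the model — other features' intensities do
not — and blanks never enter training. Post-correction QC RSDs are
recomputed and reported but never re-filter.

**RSD filter**: per-feature QC relative standard deviation (n−1 standard
deviation / mean × 100); features above 30% are removed. A zero-mean QC
feature has undefined RSD and is removed with a flag; identical QC values
(RSD 0) always survive.

**Technical averaging** collapses the study injections to one row per
(cultivar, biological replicate) by the arithmetic mean on the corrected
scale (averaging follows correction, so injection-specific metadata is
dropped); QC and blank rows leave the table here. **Autoscaling** centers
each feature to mean 0 and unit sample variance, dropping zero-variance
features with a warning and releasing the nonnegativity invariant.

The fold-change and moderated-t statistics run on the corrected *unscaled*
table (log2 for the t-test); PLS, PCA and HCA run on the autoscaled table.
A fold change on centered data is undefined, so this split is the minimal
consistent reading of "center and scale everything".

## Classification

Samples are projected onto their first 10 principal components (PCA on the
autoscaled matrix via SVD; component count capped at what the data
supports), the score coordinates are clustered by Ward.D2 on Manhattan
distances, and the tree is cut into k = 2 groups. Ward.D2 applies the
Lance–Williams recurrence to the *squared* input dissimilarities and
reports heights on the original scale — the convention is reproduced
verbatim even though Ward's derivation presumes squared Euclidean input,
because the analysis names that linkage on that metric. Cluster numbering
is deterministic: cluster 1 is the cluster with the higher grand-mean log2
intensity (computed from the unscaled table when available), reflecting the
convention that group 1 is the high-abundance group; ties go to the smaller
cluster. A per-cultivar consensus label is the majority over its
replicates. Agreement between labelings is quantified by the adjusted Rand
index.

## Statistics

**Moderated t-test.** Per feature, a two-group least-squares fit gives the
mean difference and pooled residual variance s² on d = n₁+n₂−2 degrees of
freedom. The variances are shrunk toward a prior: s²_post =
(d₀s₀² + d·s²)/(d₀+d), with (d₀, s₀²) estimated by moment-matching the
scaled-F marginal of the log sample variances — the empirical variance of
e = log s² − ψ(d/2) + log(d/2) in excess of ψ′(d/2) identifies d₀ through
the trigamma inverse (Newton iteration), and s₀² follows from the mean of
e. When no excess dispersion exists, d₀ = ∞ and s₀² is the plain mean of
the variances, making shrinkage a fixed point when all features share one
variance. The moderated statistic is referred to a t distribution on
d + d₀ df (normal for infinite d₀). The implementation agrees with a
formula-literal independent recomputation to 1e-8 and reproduces the
ordinary pooled t exactly when d₀ is forced to 0.

**BH adjustment** is the standard step-up: sorted p·m/rank, cumulative
minimum from the largest rank, capped at 1. Note the step-up map is *not*
idempotent (re-adjusting adjusted values inflates them again); the
properties that do hold — elementwise domination, cap at 1, rank
monotonicity, agreement with reference implementations — are what the
tests assert.

**Fold change** is log2(group-1 mean / group-2 mean) on the corrected
positive scale. The selection criterion is interpreted as |log2 FC| > 1 by
default: reported marker fold changes such as 0.31 or 1.06 only make sense
on a log scale, where a raw-ratio cut-off of 1 would be vacuous. The raw
ratio and signed-log readings remain selectable (`fc_mode`).

**PLS and VIP.** PLS1 by NIPALS with X-deflation; per component the weight
vector is X'y normalized, scores t = Xw, y-loading q and X-loadings
follow, and the explained response sum of squares SSYₐ = qₐ²·tₐ'tₐ is
recorded. VIPⱼ = √(p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ), whose mean square
over features is exactly 1 — the VIP > 1 criterion selects features
contributing more than an average share. The component count is tuned by
cross-validated Q² (stratified seeded folds, default 10, capped at 5
components for tractability inside the resampling loops); a label
permutation test with add-one smoothing is available for model-level
validation. The class response is coded +1/−1.

**Logistic GLM.** Binary logistic regression by iteratively reweighted
least squares with a small ridge (default 1e-3) on the slopes (intercept
unpenalized). The ridge keeps the fit finite on separable data — exactly
the situation a good marker set produces — while leaving coefficients
within 1e-6 of a generic optimizer of the same penalized likelihood.

## Nested selection

The rational cut-off selects features passing all three criteria
simultaneously: BH-adjusted moderated-t p < 0.05, |log2 FC| > 1, VIP > 1
from a component-tuned PLS fit. It is wrapped in nested resampling:

1. stratified 10-fold outer split of the 54 analysis samples;
2. per outer fold, the remaining nine folds define nine inner iterations;
   in iteration i the inner-training set (the other eight folds) is
   bootstrapped five times, stratified within class, and the cut-off runs
   on each bootstrap;
3. the five bootstrap sets are intersected per iteration, the nine
   iteration sets are intersected into the outer set S_o;
4. a logistic GLM restricted to S_o is trained on the outer-training
   samples and scored on the held-out fold (a diagnostic, not a veto);
5. the final marker set is the strict intersection of the ten outer sets.

The inner-loop topology is genuinely open to two readings; bootstrapping a
lone five-sample fold cannot support a tuned PLS fit, so the default
bootstraps the inner-*training* sets, and the literal per-fold reading
remains selectable (`inner_mode="literal"`). An empty outer set is
recorded loudly (accuracy undefined for that fold) and propagates to an
empty final set.

The selection-bias benchmark deserves a note. With labels drawn
independently of the data and default thresholds, the 45-fold intersection
almost always returns empty sets — the selector's correct answer, but one
that leaves no classifier to score. The benchmark therefore (a) loosens
the thresholds to alpha = 1, no fold-change gate, VIP > 1, so that
chance-correlated features *are* selected, and (b) scores an empty outer
fold at chance accuracy 0.5, since no markers means no classifier. Under
this protocol the nested scheme sits at 0.5 while selecting once on the
full dataset and then cross-validating on the same data inflates accuracy
to roughly 0.7–0.8 — the bias the nesting exists to remove.

## Reporting

Selected signals are grouped by single-linkage chaining on retention time
(window 0.1 min, polarity ignored so opposite-polarity ions of one
compound co-group); isotope/adduct identification proper requires
fragmentation spectra and stays out of scope. The marker table lists each
final-set feature with m/z, retention time, polarity, VIP and log2 fold
change, the latter two recomputed once on the full analysis-ready dataset.

## Benchmark problem sizes

The packaged benchmarks run the full design (180 injections per polarity,
54 analysis samples) with feature counts chosen for desk-scale runtimes:
1000 features and 10 simulated studies for marker recovery (20 markers at
2.0 log2 effect, no missingness so the experiment isolates the selector),
150 features × 3 runs for the selection-bias null, 2000 features × 200
replicates for the t-test calibration, and reduced feature counts
(50–80) in unit fixtures. Recovery is evaluated against the planted truth
groups, isolating the selector from classification noise; clustering
quality is benchmarked separately (replicates of a cultivar co-cluster in
≥95% of seeded runs at a 1.0 log2 planted effect).

## Numerical choices and degenerate inputs

* RSD uses the n−1 standard deviation; a zero-mean QC feature is removed
  with a flag rather than raising.
* Correction predictions floored at 1e-6 × QC mean; the correction
  constant 1000 is a scale convention, not a tunable.
* NIPALS stops early on rank exhaustion (weight or score norm at machine
  epsilon scale) and returns fewer components with a warning.
* Ward merges break ties toward the first minimal pair in index order,
  making the merge sequence deterministic; duplicate points merge first at
  height 0.
* Dendrogram cuts label clusters by their smallest leaf index; the
  two-cluster orientation rule is described under Classification.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived child seeds stay below 2³¹.

## Known limitations

* Per-feature correction models ignore cross-feature structure; a drift
  component shared across features is corrected feature by feature rather
  than jointly.
* The boosted correction model's hyperparameters are defaults, not tuned;
  with only ~5 QC points per batch a deliberately small tree depth guards
  against overfitting the QC trace.
* Strict intersections make the final set conservative: a marker missed in
  a single bootstrap of a single inner iteration of a single outer fold is
  lost. This matches the procedure's design intent (maximum prediction
  power, not maximum recall).
* The GLM accuracy is recorded per outer fold but never rejects a fold's
  set; an optional accuracy floor is available but off by default.
* Raw-file conversion, peak picking, alignment and compound identification
  are out of scope; the pipeline starts at the peak table.
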