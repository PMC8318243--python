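# Methods

`multlearn` predicts treatment sensitivity (TS) in multiple-myeloma-like
cohorts from clinical markers, bulk gene expression and the first-line
treatment, and then asks the counterfactual question: which treatment would
have maximized each patient's predicted sensitivity?  This note documents the
model, its assumptions, the tunable parameters, the synthetic benchmark, and
the design choices made where the procedure left genuine freedom.

## Outcome model

Treatment response (TR) is a six-class ordered outcome, by depth of response:
PD < SD < PR < VGPR < CR < SCR.  TS is a binary cut of this scale: a patient
is *sensitive* when their TR class is at or above a cutpoint.  The cutpoint is
not fixed a priori: `select_ts_definition` evaluates all five candidate cuts
and keeps the one whose TS grouping minimizes the survival-stratification
p-value against days to disease progression (DDP).  The stratification test is
the Cox partial-likelihood score test for a single binary covariate, which
equals the log-rank test (Breslow ties); we compute it with `lifelines`.
On data whose hazard genuinely breaks at the complete-response boundary the
search selects {CR, SCR} as the sensitive class, which is also the package's
default when no survival data is available.  Ties across cuts resolve to the
lowest cut index.

## Preprocessing

Nominal clinical markers are one-hot encoded (one 0/1 column per level),
ordinal markers map to sequential integers starting at one, and missing values
become zero.  Missingness is measured **before** zero-imputation: markers
missing in more than 10 % of patients are dropped first, then the survivors
are zero-filled (otherwise the 10 % rule would be vacuous).  Patients without
a TR response are excluded, as are entire treatments carrying fewer than 10
patients.  Every feature is min–max normalized with bounds learned on training
data only; validation data is transformed as `min(1, max(0, n(m)))`.  Constant
markers map to 0 (the formula's denominator is zero; the marker carries no
information).  Patients are always ordered lexicographically by id.

## Marker selection

For each marker, a two-sample two-sided Kolmogorov–Smirnov test compares its
distribution between the TS classes; markers with p > α (default α = 0.05,
configurable — an appropriate value depends on the marker count and desired
stringency) are irrelevant.  Relevant markers are then pruned for linear
redundancy: if two relevant markers have |Pearson r| > β (default 0.75), the
one with the larger KS p-value is excluded and recorded as redundant to the
other.  The sweep processes markers most-significant first (ascending
p-value, ties lexicographic by name), comparing each anchor only against
markers not yet analysed and skipping markers already excluded.  Under this
order the kept member of every compared correlated pair is the more
significant one and the output is fully deterministic; p-values are computed
once per marker and cached.  No second pruning pass is made, so two survivors
whose pairwise comparison was never anchored can in principle remain
correlated; the test suite pins the exact behaviour against a literal replay
oracle instead of asserting a pairwise-decorrelation guarantee the procedure
does not make.  Pearson correlation with a zero-variance vector is defined
as 0.  Selection runs separately over clinical markers (→ C′) and genes
(→ G′).

## Feature extraction

Three branches expand the selected genes G′:

* **Genetic profiling (GP)** — k-means over patients; the features are each
  patient's Euclidean distances to the `o` centroids (block L).
* **Gene clustering (GC)** — k-means over genes (the transposed matrix); the
  features are each patient's mean expression per gene cluster (block E).
* **Gene denoising (GD)** — a denoising autoencoder reconstructs G′ from
  noise-corrupted input (block G^d).

Cluster counts `o` and `k` are chosen independently by NCS, which scans
c = 2, 3, … maximizing `SCM(c) = (mean(SC) − sd(SC)) / (sd(cluster sizes) + 1)`
and stops after 10 consecutive counts without a new maximum.  Both standard
deviations are population (divide-by-n) deviations — well-defined even for a
single vector of cluster sizes.  Silhouettes use Euclidean distance,
consistent with GP.  k-means uses k-means++ with 10 restarts and a fixed
seed; NCS argmax ties go to the smallest count (parsimony).  Centroids and
gene assignments are frozen at training time; validation patients are
projected without refitting.

The autoencoder has layer widths `[i, ⌊0.5i⌋, ⌊0.4i⌋, ⌊0.3i⌋, ⌊0.4i⌋,
⌊0.5i⌋, i]` where `i = |G′|`, ReLU hidden activations, a linear output,
additive standard-normal input noise resampled every epoch, full-batch
AdaDelta (ρ = 0.95, ε = 1e−6), and an L2 weight penalty with coefficient
0.01.  Training stops after `patience` (default 1000) epochs without a new
minimum reconstruction MSE, capped at `max_iter` (default 5000) epochs; the
weights at the minimum are kept.  It is implemented directly in NumPy with
hand-written backpropagation — the network is small enough that a framework
would add nothing.  Inference is a deterministic forward pass on clean
inputs.  Branches degrade gracefully when G′ is small: profiling needs ≥ 2
genes, gene clustering ≥ 3, the denoiser ≥ 4 (so every floor width is ≥ 1).

## Predictor training

The final feature block is the concatenation `G′ | C′ | L | E | G^d | T`,
where T is the one-hot treatment block (treatments are nominal, so they
follow the nominal encoding rule; T bypasses marker selection).  Training has
two phases:

1. **Hyperparameter optimization.**  Gaussian-process Bayesian optimization
   minimizes the validation log loss of a LightGBM classifier over a
   stratified half-split of the training data (half trains, half scores).
   The optimizer draws 10 random points, then fits a Matérn-5/2 GP surrogate
   on the observed losses and proposes the expected-improvement maximizer
   among randomly sampled candidates, for 50 further evaluations; it returns
   the global-minimum point and the full trace.  A failing objective is
   recorded as +∞ and skipped when fitting the surrogate.  The search space
   covers `num_leaves`, `scale_pos_weight`, `min_child_samples`,
   `bin_construct_sample_cnt`, `max_bin`, `min_sum_hessian_in_leaf`,
   `bagging_fraction`, `feature_fraction` and `feature_fraction_bynode`,
   with standard practitioner ranges (log-scaled where the parameter spans
   decades).
2. **Ensemble fit.**  The training data is split into three stratified folds;
   one boosted-tree model is trained per pairwise fold union with the
   optimized hyperparameters, early-stopped on the held-out third's log loss
   (patience 1 round, at most 100 boosting iterations).  The TS score is the
   arithmetic mean of the three members' scores, always in [0, 1].

The decision threshold is learned on training data only: a scan over the
midpoints of adjacent sorted unique training scores picks the threshold
maximizing Youden's J (sensitivity + specificity − 1), the ROC point a
"highest-AUC threshold" denotes; ties go to the lower threshold, and a
degenerate all-equal score vector returns that value with J = 0.

The **SMLA baseline** is the same skeleton without extraction: marker
selection, Bayesian optimization of a single classifier (LightGBM, MLP or
SVM, each with its own search space), a final fit on all training data, and
the same threshold rule.  Log loss uses ε = 1e−15 probability clipping.

## Evaluation

Cross-validation stratifies patients by treatment × TS cell.  Before fold
assignment, the majority TS class within each treatment stratum is randomly
undersampled to the minority count (undersampling rather than oversampling —
no patient is ever duplicated), and the retained patients of each cell are
dealt round-robin into the folds, so per-cell fold sizes differ by at most
one.  Each fold's entire pipeline — normalization bounds, selection,
clustering, denoiser, optimization, threshold — is fit on the nine training
folds only; a corruption audit in the test suite verifies that altering
validation-fold labels and features leaves every training artifact
byte-identical.  AUC uses the rank (Mann–Whitney) formulation; hard-label
metrics use each fold's own training-derived threshold; per-treatment metrics
pool all validation scores into one table.  Fold-level AUC vectors of two
pipelines run under the identical fold plan are compared with a two-sample
t-test.

The marker-relationship graph aggregates per-fold selection reports: node
size is the number of folds a marker was selected, node intensity is
1 − (mean p-value across those folds), shape role tags clinical vs gene, and
edge width counts co-selection folds (zero-width edges omitted).

## Treatment simulation

For each validation patient and each candidate treatment, the one-hot
treatment block of the feature row is overwritten with the candidate and the
TS score recomputed; nothing else changes and the cohort is never mutated.
κ is the score-maximizing treatment; ζ = 1 when κ differs from the actual
treatment; the switch fraction is the mean of ζ.  On an exact score tie the
actual treatment wins if it is among the maximizers, otherwise the
lexicographically first maximizer — a conservative rule that never reports a
switch on a tie, so a treatment-blind predictor yields a switch fraction of
exactly 0.  The reallocation matrix gives, per actual treatment a, the
percentage of its patients reassigned to each simulated treatment b; rows sum
to 100.  In cross-validation the simulation runs per fold with that fold's
predictor on its own validation patients, then pools.

## Synthetic benchmark

The generator emulates the structure the pipeline keys on, with defaults
chosen as the study conditions: 500 patients; five first-line treatments with
uneven prevalence proportional to a realistic newly-diagnosed mix
(Bor-Cyc-Dex 133 : Bor-Dex 64 : Bor-Len-Dex 236 : Len-Dex 50 :
Non-treatment 232); a sensitive fraction of 0.25 (CR/SCR is the minority
outcome); 500 genes of which 10 are informative with a 1-sd log-space shift
between TS classes, each shadowed by one tightly correlated duplicate
(log-space noise sd 0.05 by default); 10 clinical markers of which 3 are
informative; 5 % missing clinical values (expression is complete, matching
how quantified expression matrices arrive); exponential DDP times with a
hazard ratio of 3 between TS classes and 20 % censoring.  Expression is drawn
log-normally to mimic RNA-seq abundance skew while staying non-negative; KS
selection is invariant to this monotone transform.  TR classes come from
thresholding a latent response propensity into six ordered bins such that the
planted TS is exactly the CR/SCR cut.  An optional treatment × biomarker
interaction plants a responsive subgroup (latent biomarker > 0, loading onto
a subset of informative genes) whose sensitivity probability rises by `shift`
only under one specific treatment; the ground-truth record marks these
patients and their latent optimal treatment so counterfactual recovery can be
scored directly.  An optional FISH-like panel thresholds noisy linear scores
over driver-gene expression at a target prevalence.

What the generator does **not** emulate: real marginal distributions or gene
identities, batch effects, library-size artifacts, correlated clinical
missingness, competing risks, or informative censoring.  Passing tests
demonstrate that the machinery recovers planted structure under its stated
assumptions, not that the pipeline attains any particular accuracy on real
myeloma cohorts.

## Numerical and scaling choices

* Seeds: one master seed fans out to per-stage seeds through hashed seed
  sequences (`derive_seed`), so every stochastic stage is independently
  reproducible; all derived seeds are below 2³¹.
* KS p-values use the exact small-sample distribution when feasible (SciPy's
  automatic switch), asymptotic otherwise.
* The `MultSettings.fast()` preset (5 + 8 BO evaluations, NCS capped at 8
  clusters with a 5-step stall, denoiser patience 100 / 600 epochs) is the
  problem size used by the bundled demonstrations, tests and the acceptance
  script; defaults follow the full procedure (10 + 50, stall 10,
  patience 1000).
* If a fold's three-way stratified split leaves a member without both
  classes, the split is retried with a shifted seed (up to 5 attempts).
* `bin_construct_sample_cnt` and `bagging_fraction` interact with LightGBM's
  `bagging_freq`, fixed at 1 so bagging is active whenever sampled below 1.

## Known limitations

* The redundancy prune is single-pass by construction; see above.
* The BO candidate pool is random sampling (512 points per iteration), not a
  gradient-based acquisition optimizer; adequate at these dimensionalities.
* SVM probabilities come from Platt scaling, whose calibration on the small
  equalized training sets is rough; this affects the SMLA-SVM baseline's log
  loss, not its AUC ranking.
* Per-treatment validation metrics can rest on few patients for rare
  treatments; AUC is reported as NaN when a treatment's validation pool lacks
  one of the classes.
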