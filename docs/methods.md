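# Methods

`refsig` implements a cross-study biomarker-discovery workflow for 16S
rRNA amplicon data in which the feature unit is the exact amplicon
sequence variant (ASV) string. Because ASVs are denoised exact sequences,
a feature selected in one study can be looked up in an independent study
by sequence identity — the property the whole workflow is built on.

## Data model

A dataset is a samples × features count matrix with binary group labels
(0 = control, 1 = case) and one uppercase DNA sequence per feature; the
sequence *is* the feature identity, and taxonomy is at most display
metadata. Counts stay raw integers: no rarefaction or compositional
transform is applied by the data layer. Scaling is a modelling concern
and happens inside each cross-validation fold (standardisation fitted on
the training portion only), because several of the classifiers used are
scale-sensitive. Eligibility for selection or validation requires at
least 10 samples per group.

The discovery dataset among a family of ≥ 3 is the one whose ASV
sequences are shortest, summarised as the smallest **median** feature
length, tie-broken by smallest mean, then by input order. The median was
chosen over the minimum or mean because a handful of unusually short or
long ASVs should not decide eligibility. Sequence length is measured on
the processed ASVs (what the package actually ingests), not on raw
reads. The shortest-trim dataset is the only one whose features can be
*contained* in the others', which is why it must anchor discovery.

## REFS — recursive ensemble feature selection

Features are scored by an ensemble of eight heterogeneous scikit-learn
classifiers: an SGD-trained linear model, a linear-kernel SVC, gradient
boosting, random forest, logistic regression, a passive-aggressive
linear classifier (instantiated through its SGD formulation), a ridge
classifier, and bagged decision trees. Per classifier, the per-feature
importance is |coefficient| for linear members and impurity importance
for tree members; each importance vector is L1-normalised so every
classifier votes with equal weight, then summed. At each elimination
step the top `ceil(0.8·|F|)` features are retained (ties broken by
original feature order; the step is forced to shrink by at least one
feature, since the ceiling stalls below five features), down to a floor
of one feature. The 0.8 keep fraction is configurable; geometric
shrinkage visits ~35 sizes from 2040 features down to 1, which gives the
accuracy curve useful resolution without quadratic cost.

The accuracy trajectory is estimated by nesting the elimination inside
stratified 10-fold cross-validation: each fold runs its own elimination
path on its training portion only, and accuracy at every feature count
is measured on that fold's untouched held-out samples. The trajectory
point at size *s* is the mean over all fold × classifier held-out
accuracies. This nesting matters: a single pooled elimination loop that
reuses cross-validated importances to prune and then reports the pruned
sets' CV accuracy lets every sample influence the surviving feature set,
and on label-permuted data such a loop drives the apparent trajectory
maximum far above chance (the classic selection-induced optimism of
recursive elimination). With per-fold paths the permuted-label
trajectory stays at chance level, which is the behaviour the package's
null tests assert.

The reported feature set comes from a parallel elimination path run on
the complete dataset, cut at the trajectory size with maximal mean
accuracy (ties toward fewer features) — the standard way a
recursive-elimination selector converts an unbiased CV curve into one
concrete signature. Within a run, one classifier seed is drawn and
shared by every step (common random numbers), so that accuracy
differences along the trajectory reflect the feature sets rather than
reseeded classifier noise.

The whole procedure repeats `n_runs` (default 10) times with seeds
`seed+0 … seed+n_runs−1`; the reported signature is the best-accuracy
run's set (ties: fewer features, then lower run index), and per-feature
agreement across runs is reported as a stability diagnostic. The roster
members use moderate ensemble sizes (25 boosting stages of depth-2 trees
with √p feature subsampling, 25 random-forest trees, 10 bagged trees):
the ranking signal is aggregated over 8 classifiers × 10 folds × many
steps, so per-model ensemble size adds little once past a few dozen
members, while the roster is refit at every step of every fold path.

## Validation module

A selected feature set is judged by five classifiers disjoint from the
selection ensemble — AdaBoost (15 stumps), Extra Trees (25 trees),
k-nearest neighbours, a one-hidden-layer perceptron (30 units), and
LassoCV — under stratified 10-fold cross-validation, repeated `n_runs`
(default 10) times with distinct seeds. Per classifier:

* **AUC** — per-fold ROC curves from held-out continuous scores
  (class-1 probability where available, decision value otherwise;
  LassoCV is treated as a continuous regressor on the 0/1 labels whose
  prediction is the score and whose hard label is score > 0.5). Fold
  curves are vertically averaged on a fixed 101-point false-positive-rate
  grid; the AUC is the mean of per-fold trapezoidal AUCs, which equals
  the Mann–Whitney pairwise statistic with ties counting ½.
* **MCC** — Matthews correlation of the pooled out-of-fold hard
  predictions of a run (one confusion table per run, defined as 0 when a
  denominator factor vanishes). Pooling avoids undefined per-fold MCCs
  when folds are small.

The headline numbers are the arithmetic means of the five per-classifier
values. The module is run once with the selected features and once with
all features; on high-dimensional noisy tables the all-features run is
expected to score substantially lower — that contrast is the point of
the comparison.

## Cross-dataset testing

A discovery sequence *s* matches a testing feature *t* iff *s* is a
contiguous substring of *t*, uppercased, with exact characters (IUPAC
ambiguity codes match only themselves). No reverse-complement or
mismatch-tolerant search is attempted by default — exact containment is
the strict reading of sequence-identity matching; a bidirectional mode
(additionally accepting *t* inside *s*) exists behind a flag. When *s*
occurs in *n* testing features, their per-sample abundances are summed
into one aggregated column; a testing feature matched by two signature
sequences contributes to both columns. The matched sub-table is then
validated with the 5-classifier module on the testing dataset's labels.

## Baselines

* **K-Best** ranks discovery features by the two-group one-way ANOVA F
  statistic on raw counts (F = 0 when within-group variance vanishes)
  and keeps the top *k*, where *k* equals the REFS signature size. The
  K-Best signature is carried to testing datasets with the same
  containment rule.
* **Random selection** draws *m* features uniformly without replacement
  from the testing dataset, *m* being the number of REFS signature
  features actually found there, 10 times with seeds `seed+0 … seed+9`,
  validating each draw.

## Synthetic data generator

The generator emulates a family of linked 16S studies: background counts
are i.i.d. negative binomial (mean `base_mean` = 50, dispersion α = 0.5,
variance μ + αμ²) — the standard overdispersed model for microbiome
counts; `n_signal` planted features have their case-group mean
multiplied by `2^log2_fold_change` (default log2FC = 2). Each dataset
has its own ASV length (`trim_lengths`; the unique minimum marks the
discovery dataset). Planted sequences are generated at the discovery
length and embedded with random flanks inside testing features; per
testing dataset, `dropout_signal` planted sequences get no containing
feature and `n_duplicated_matches` are embedded in exactly two features,
so the matching stage's summation and dropout handling are exercised by
construction. Testing datasets optionally receive a global multiplicative
mean shift `exp(batch_log_shift)` — the minimal mechanism for a
between-study batch effect. Sequences are i.i.d. uniform DNA.

Default group sizes are 50/50 with 500 features, mirroring a mid-sized
amplicon study. What the generator deliberately does **not** model:
compositional coupling between taxa, phylogenetic correlation, sparsity
structure (zero inflation), library-size variation, and partial or
mutated sequence overlap between studies. Passing tests on this
generator therefore demonstrate the machinery's correctness and the
methodology's behaviour under clean planted signal, not performance on
real microbiome data.

Because discovery and testing datasets share *only* the planted
sequences, any selector that captures the planted set produces the same
matched testing table: once both REFS and K-Best recover all planted
features, their cross-dataset validation results coincide, and on this
generator K-Best is expected to track REFS closely rather than trail it
as it does on real data (where univariate F ranking and multivariate
ensemble ranking diverge). The random baseline, by contrast, almost
never draws matched-signal columns and sits near chance.

## Problem sizes and numerical choices

Test-suite experiments run at desk scale, chosen as the smallest sizes
at which the statistical claims are still sharp: recovery and null
checks use 100-sample datasets with 150–500 features; the comparative
protocol uses 30-sample, 150-feature families; unit fixtures are smaller
still. All randomness flows from explicit integer seeds; repeated runs
of any stage with the same configuration are bit-identical. Ties in
feature ranking always fall back to original feature order. Degenerate
inputs (constant labels, single-class folds, empty signatures, zero-
variance features, all-classifier fit failure) raise typed errors or are
given defined values (MCC = 0, F = 0) as documented in the docstrings.

## Known limitations

* The selection rule "fewest features at maximal accuracy" is applied to
  a noisy curve; when the true accuracy curve has a flat top the chosen
  size fluctuates across the plateau between runs. The per-feature
  run-agreement diagnostic exists to make that visible.
* LassoCV as a classifier (regress on 0/1, threshold at 0.5) is a
  pragmatic convention; its MCC is sensitive to the threshold.
* Containment matching is exact: a single substitution inside an
  otherwise identical ASV breaks the match. This is by design (ASVs are
  exact sequences) but means primer/denoising differences between
  studies can reduce the matched fraction.
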