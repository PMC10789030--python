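# refsig

Reproducible biomarker discovery for 16S rRNA microbiome studies:
recursive ensemble feature selection (REFS) on ASV abundance tables,
multi-classifier validation, and cross-dataset signature testing by
sequence containment.

## The problem

Microbiome case/control studies routinely produce classifiers that do
not transfer: OTU clusters are not comparable across studies, pipelines
differ, and feature selection on a single high-dimensional, small-n
table overfits. `refsig` works at the level of exact amplicon sequence
variants (ASVs), whose sequences are directly comparable between
independent studies, and organises the analysis so that a biomarker
signature is *selected* in one dataset and *re-validated* in others:

1. **Discovery selection** — among ≥ 3 datasets, the one with the
   shortest ASV sequences (smallest median length) anchors discovery, so
   its sequences can be found inside the longer sequences of the others.
2. **REFS** — an ensemble of 8 classifiers (SGD linear model,
   linear-kernel SVC, gradient boosting, random forest, logistic
   regression, passive-aggressive, ridge, bagged trees) is trained under
   stratified 10-fold cross-validation; L1-normalised feature
   importances are aggregated and the bottom 20% of features dropped,
   recursively. Elimination runs nested per fold so the resulting
   accuracy-vs-feature-count trajectory is never contaminated by
   selection. The signature is the smallest feature set at maximal
   cross-validated accuracy, over 10 repeated runs.
3. **Validation** — 5 independent classifiers (AdaBoost, Extra Trees,
   KNeighbors, MLP, LassoCV) under stratified 10-fold CV report
   per-classifier and averaged AUC and MCC, for the selected features
   and for all features.
4. **Testing** — each signature sequence is searched in every testing
   dataset by exact substring containment; a sequence present in *n*
   testing features gets their abundances summed, and the matched
   sub-table is re-validated on the testing dataset's own labels.
5. **Baselines** — K-Best by ANOVA F-score (k = signature size) and a
   10-time random feature selection (m = number of signature features
   found) put the numbers in context.

A negative-binomial synthetic-data generator produces linked dataset
families with a planted signature (configurable effect size, dispersion,
per-dataset trim length, dropout, duplicated matches, batch shift), so
the entire workflow is testable without downloading any accession.
See `docs/methods.md` for models, parameters, and limitations.

## Worked example

```python
from refsig import (
    SyntheticSpec, generate_dataset_family, refs_select, RefsConfig,
    validate_features, test_signature, select_discovery_dataset,
)

spec = SyntheticSpec(          # 3 linked datasets, 10 planted ASVs
    n_control=50, n_case=50, n_features=500, n_signal=10,
    log2_fold_change=2.0, dispersion=0.5,
    trim_lengths=(100, 150, 150), batch_log_shift=0.5, seed=20260,
)
family, truth = generate_dataset_family(spec)

disc = family[select_discovery_dataset(family)]
result = refs_select(disc, RefsConfig(n_runs=10, seed=0))
print(len(result.selected.sequences),
      len(set(result.selected.sequences) & set(truth.sequences)))
# 7 7    <- a 7-feature signature, every feature a planted ASV

report = validate_features(disc, result.selected, n_runs=10, seed=0)
print(round(report.average_auc, 3), round(report.average_mcc, 3))
# 1.0 0.989    <- averaged over AdaBoost/ExtraTrees/KNN/MLP/LassoCV

match, test_report = test_signature(result.selected, family[1],
                                    n_runs=10, seed=0)
print(match.matched_count, round(test_report.average_auc, 3))
# 5 0.995    <- 5 of the 7 sequences found by containment (the testing
#               dataset drops 2 planted sequences by construction),
#               abundances of duplicated occurrences summed, and the
#               matched table re-validated on the testing labels
```

The same stages are available as a CLI over TSV/FASTA triples
(counts table, ASV FASTA, labels):

```bash
refsig simulate --outdir sim --seed 1
refsig refs     --counts sim/synthetic_d0_counts.tsv \
                --fasta sim/synthetic_d0.fasta \
                --labels sim/synthetic_d0_labels.tsv --outdir refs_out
refsig test     --counts sim/synthetic_d1_counts.tsv \
                --fasta sim/synthetic_d1.fasta \
                --labels sim/synthetic_d1_labels.tsv \
                --signature refs_out/signature.fasta --outdir test_out
refsig run      --config docs/example_experiment.yaml   # full pipeline
```

`refsig run` emits the elimination trajectory (TSV + plot), the
signature FASTA, per-dataset match reports, per-method validation tables
in a classifier × {AUC, MCC} layout, mean-ROC plots, and a
reproducibility manifest (config hash, seeds, versions).

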