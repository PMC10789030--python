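# Example config for `refsig run`. Paths are the standard triple per
# dataset (counts TSV, ASV FASTA, labels TSV), e.g. as written by
# `refsig simulate`. The discovery dataset is picked automatically
# (shortest median ASV length) unless discovery_override names one.
datasets:
  - name: study_a
    counts: sim/synthetic_d0_counts.tsv
    fasta: sim/synthetic_d0.fasta
    labels: sim/synthetic_d0_labels.tsv
  - name: study_b
    counts: sim/synthetic_d1_counts.tsv
    fasta: sim/synthetic_d1.fasta
    labels: sim/synthetic_d1_labels.tsv
  - name: study_c
    counts: sim/synthetic_d2_counts.tsv
    fasta: sim/synthetic_d2.fasta
    labels: sim/synthetic_d2_labels.tsv

refs:
  n_folds: 10
  reduction_keep_fraction: 0.8
  min_features: 1
  n_runs: 10
  seed: 0

validation_runs: 10
seed: 0
match_mode: forward       # or "bidirectional"
run_baselines: true
random_runs: 10
output_dir: refsig_out
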