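# liquidmrd

A liquid-biopsy minimal-residual-disease (MRD) analysis pipeline for serial
plasma / white-blood-cell (WBC) targeted sequencing in a neoadjuvant trial
setting. The package covers:

- **Cohort I/O** (`liquidmrd.io`) — typed data model and TSV dialects for
  variant observations, sample manifests, COSMIC-style occurrence
  annotations, and clinical outcomes, with strict validation and
  byte-deterministic writers. Optional single-sample VCF ingest.
- **Variant-origin classification** (`liquidmrd.classify`) — the
  WBC-informed decision tree assigning each patient-variant a germline,
  clonal-hematopoiesis (CH), or tumor origin from hotspot status (>= 25
  registry occurrences), the >= 25% allele-fraction germline pattern, WBC
  super-mutant-count bands (>= 3 / 0 / 1-2), and the hematologic/lymphoid
  occurrence share (10% cutoff). Every call carries an auditable rule path.
- **ctDNA status calling** (`liquidmrd.status`) — per-timepoint
  detected/undetected calls at any allele fraction, cell-free tumor load
  (max or mean MAF of tumor variants), patient evaluability (undetectable
  = UD group), and clearance/persistence trajectory patterns.
- **Outcome statistics** (`liquidmrd.stats`) — pathological regression
  grading (G0-G3, pCR/MPR), Kaplan-Meier with Greenwood variance and
  complementary log-log confidence bounds, k-sample log-rank, exact
  (Clopper-Pearson) binomial confidence intervals, Fisher's exact and
  Wilcoxon rank-sum tests, and survival comparisons grouped by ctDNA status.
- **Bayesian trial monitoring** (`liquidmrd.monitoring`) — beta-binomial
  posterior exceedance rules, prior calibration from a stated mean and tail
  probability, and stopping-boundary tables.
- **Synthetic cohorts** (`liquidmrd.simulate`) — fully synthetic serial
  variant / manifest / annotation / outcome tables with planted origins,
  clearance timepoints, assay false negatives, and survival effects, plus
  ground-truth tables for recovery scoring.
- **CLI** (`liquidmrd.cli`) — `simulate`, `classify`, `status`, `outcomes`,
  `monitor`, and `run` (all stages end-to-end with a config file).

## CLI quick start

```sh
# generate a synthetic cohort
liquidmrd simulate --out-dir sim --seed 7

# run all stages
cat > pipeline.yaml <<EOF
variants: sim/variants.tsv
manifest: sim/manifest.tsv
cosmic: sim/cosmic.tsv
outcomes: sim/outcomes.tsv
EOF
liquidmrd run --config pipeline.yaml --out-dir out

# inspect
cat out/report.md
```

Individual stages (`classify`, `status`, `outcomes`, `monitor`) run on
pre-existing intermediate files; see `liquidmrd <cmd> --help`.

## File dialects

- `variants.tsv`: `patient_id sample_id chrom pos ref alt gene
  maf_fraction|maf_percent distinct_coverage super_mutant_count`
- `manifest.tsv`: `sample_id patient_id material timepoint collection_day`
  (`material` in PLASMA/WBC; `timepoint` in BASELINE/D14/POST_ICI/PREOP/POSTOP)
- `cosmic.tsv`: `chrom pos ref alt total_occurrences heme_lymphoid_occurrences`
- `outcomes.tsv`: `patient_id arm resected residual_viable_tumor_pct
  rfs_months rfs_event os_months os_event pd_l1_cps lag3_log2_expression`

MAF is stored internally as a fraction in [0, 1]; coordinates are 1-based
VCF-style with indel left-normalization on ingest.
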