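# tfdynamics

Site-specific transcription factors (TFs) — a few percent of an animal
genome — orchestrate development through when and where they are expressed.
`tfdynamics` is a Python package for the system-wide analysis of TF
expression dynamics across embryogenesis in the style of the *Drosophila*
regulatory-genomics literature: it classifies each gene's temporal
expression pattern over the six embryonic stage-range windows of in situ
annotation (stages 1-3, 4-6, 7-8, 9-10, 11-12, 13-16), quantifies TF
over-representation per tissue, measures tissue specificity, counts
precisely co-expressed TF modules and their conservation across stages, and
tracks two-factor ChIP co-occupancy transitions at genomic sites.

It is aimed at computational biologists who want these statistics as tested,
reusable components rather than one-off scripts, and at method developers
who need a fully synthetic benchmark: the package ships generators for all
five input modalities (gene catalog, stage × tissue annotations, time-course
log-ratios, replicate present/absent + up/down call tables, ChIP peak BED
files) with planted, recorded ground truth.

## The statistics at its core

**Temporal classes.** A gene's binary support over the six stage ranges is
assigned one of six classes by support shape — no expression, early only,
late only, continuous zygotic, maternal + continuous, diverse — a total
classification of all 2⁶ supports.

**Enrichment Z-scores.** For a tissue cell with *n* expressed TFs and *m*
non-TFs, the TF count is standardized against random draws of *n + m* genes
without replacement from the gene universe (N genes, K TFs):

    Z = (n − d·K/N) / sqrt( d·(K/N)(1−K/N)(N−d)/(N−1) ),   d = n + m

computed either by Monte-Carlo sampling (default 10⁴ iterations) or the
exact hypergeometric closed form; a cell is significant iff Z ≥ 3.  The same
machinery scores repertoire overlap between tissues, where negative Z means
avoidance.

**Co-expression modules.** Genes with *identical* tissue annotation at a
stage form groups; modules of k = 2 or 3 genes are counted as Σ C(|group|, k),
and a module is conserved if its members are co-grouped again at the next
stage.  Significance comes from reshuffling the later stage's gene labels
(1,000 iterations): z = (observed − null mean)/null sd.

**ChIP co-occupancy.** All peaks of two factors at two timepoints are merged
(single-linkage, ≥ 1 bp) into a disjoint site universe; each site is
A-only / B-only / double / none per timepoint and transition fractions are
tabulated per origin state.

See `docs/methods.md` for definitions, defaults, and numerical conventions.

## Worked example

Simulate every modality at the default study conditions (2,000 genes, 5%
TFs, maternal fraction 0.5) with a planted 6× TF enrichment in the ventral
nerve cord at stages 13-16 and ten planted co-expression groups of four TFs
conserved with probability 0.9, then run every stage:

```sh
cat > config.yaml <<EOF
enrichment_spec:
- [ventral nerve cord, "13-16", 6.0]
n_coexpression_groups: 10
coexpression_group_size: 4
conservation_spec: 0.9
EOF
tfdyn run-all --config config.yaml --seed 11 --iterations 500 \
      --linkage-cut 0.7 --outdir out/
```

which writes the synthetic inputs, per-stage tables and `report.json`, and
prints:

```json
{
 "chip_a_only_to_double": 0.3567961165048544,
 "chip_double_retained": 1.0,
 "maternal_tf_fraction": 0.72,
 "module_z_by_transition": {
  "1-3->4-6": 43.658898599851156,
  "11-12->13-16": 47.09461209328873,
  "4-6->7-8": 47.08199069085928,
  "7-8->9-10": 49.190540579027136,
  "9-10->11-12": 53.155561497081464
 },
 "n_adult_clusters": 7,
 "n_enrichment_cells": 186,
 "n_genes": 2000,
 "n_significant_cells": 12,
 "n_tfs": 100,
 "peak_tf_share": 0.07038123167155426,
 "peak_tf_share_ratio_timecourse": 1.0661764705882353,
 "peak_tf_share_stage": "1-3",
 "temporal_class_counts": {
  "continuous_zygotic": 386,
  "diverse": 426,
  "early_only": 231,
  "late_only": 288,
  "maternal_continuous": 525,
  "no_expression": 144
 },
 "ubiquity_pooled_chi2": 11.008251764930199,
 "ubiquity_pooled_p": 0.0009070715907718886
}
```

Reading the numbers: the planted 1/3 A-only→double ChIP transition is
recovered at 0.357 from ~1,000 A-only sites, and double-occupied sites are
retained with probability 1 as planted.  The conserved co-expression groups
drive permutation z ≈ 44-53 at every transition.  The seven planted adult
up-call clusters are recovered exactly.  The maternal TF fraction (0.72)
exceeds the 0.5 baseline because the 40 planted group members are forced to
continuous (hence maternal) expression; the significant enrichment cells
include the planted ventral-nerve-cord cell plus the group signature terms,
which are genuinely TF-enriched by construction.

Single stages are available as subcommands (`simulate`, `calls`, `temporal`,
`enrich`, `overlap`, `specificity`, `modules`, `chip`, `worked-examples`);
run `tfdyn COMMAND --help` for the file formats each expects.

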