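# luadproteo

Biomarker discovery from label-free quantitative proteomes of lung
adenocarcinoma (LUAD) tissue cohorts: tumor samples paired with adjacent
normal tissue (NAT) plus benign lung-disease controls.

Label-free MS intensity matrices carry two signals at once — how abundant a
protein is where it was measured, and *whether* it was detected at all,
which in these data is itself abundance-driven (missing-not-at-random).
This package implements the full analysis chain a tissue-proteome biomarker
study runs over such a matrix, for analysts who want each stage scriptable,
auditable and testable:

- **Normalization** — log2 transform, NA-tolerant quantile normalization onto
  a mean-quantile reference, gene-level collapse (mean over protein
  isoforms), and two missingness policies: a <50%-missing filter without
  imputation for differential testing, and a <70%-missing (tumor or
  early-stage scope) filter with global-minimum imputation for biomarker
  screening.
- **Detection-frequency sets** — LUAD-related proteins (LRP: identified in
  >70% of tumors and <30% of non-tumors) and the mirrored non-tumor set
  (NDRP), computed before any imputation.
- **Differential expression** — two-sided Wilcoxon rank-sum per gene with the
  fold change defined as the ratio of group medians
  (`fc = 2^(median_a − median_b)` on the log2 scale) and Benjamini–Hochberg
  correction.
- **Survival** — Kaplan–Meier product-limit estimates, Mantel–Cox log-rank,
  and a per-gene median-split screen that labels a gene *poor-prognosis* when
  its high-expression arm has the worse observed/expected event ratio.
- **Screening cascades** — prognostic (detection > 70% of tumors → top-1,000
  abundance → >4-fold, p < 0.05 → poor-prognosis log-rank), early-stage
  diagnostic (stage-I scope, FDR-gated, restricted to a secretome gene set),
  the shared / stage-I-unique up-regulation partition, and a gradual
  stage-trend screen. Every gene's full boolean trail through each cascade is
  emitted, so `candidate == AND(filters)` is an auditable invariant.
- **Gene-dependency annotation** — median CERES essentiality score across a
  user-supplied panel of LUAD cell lines, flagged below −0.6.
- **Synthetic cohorts** — a generator with MNAR logistic detection, planted
  fold changes, stage-linked effects and hazard-linked survival, plus a
  ground-truth manifest, so the whole chain is testable without any external
  data.

## Worked example

```python
from luadproteo import (CohortConfig, DE_POLICY, apply_missing_policy,
                        collapse_to_gene_level, differential_table,
                        generate_cohort, truth_recovery_report)

matrix, ann, truth = generate_cohort(
    CohortConfig(n_patients_paired=40, n_benign=6, n_proteins=2000,
                 n_extra_isoforms=80, de_log2fc_range=(3.0, 3.0),
                 de_frac_down=0.0, seed=7))
gene = collapse_to_gene_level(matrix)
de = differential_table(apply_missing_policy(gene, ann, DE_POLICY),
                        ann, ("tumor", "nontumor"), fc_cut=2.0, p_cut=0.05)
print(int(de["up"].sum()), "up-regulated genes")
rep = truth_recovery_report(de.index[de["up"]], truth.de_genes, gene, ann)
print(rep.sensitivity, rep.specificity)
```

prints

```
32 up-regulated genes
0.7407407407407407 0.9936974789915967
```

32 genes pass the 2-fold / p<0.05 gate; 20 of the 27 detectable planted
8-fold effects are among them (sensitivity 0.74 on the unimputed matrix —
detection-limit truncation inflates non-tumor medians and shrinks apparent
fold changes; the imputed biomarker chain recovers >99%, see
`docs/methods.md`), and 99.4% of null genes are correctly left unflagged.

The `examples/` directory has one short script per capability (simulation,
normalization + frequency sets, differential expression, survival screening,
full pipeline); each prints the numbers it computes and what they mean.

## Command line

```bash
luad-proteo-screen simulate --seed 7 --out-prefix cohort
luad-proteo-screen normalize --input cohort_matrix.tsv --annotation cohort_annotation.tsv \
    --scale log2 --policy paper_de --out gene_matrix.tsv
luad-proteo-screen diffexp --gene-matrix gene_matrix.tsv --annotation cohort_annotation.tsv \
    --contrast tumor:nontumor --fc 2 --p 0.05 --out de.tsv
luad-proteo-screen run --config config.yaml   # full pipeline + manifest.json
```

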