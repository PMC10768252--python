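# Methods

## Data model

A cohort is a protein × sample matrix of log2 intensities with missing
cells, plus per-sample annotation: group (TUMOR / NAT / BENIGN), tumor/NAT
pairing by patient, TNM stage and histologic subtype for tumors, and
overall-survival (OS) and disease-free-survival (DFS) time/event pairs for
tumors only. Missingness is informative: in label-free MS a protein below
the instrument's effective detection limit is simply not identified, so
non-detection correlates with low abundance (missing-not-at-random, MNAR).

## Normalization chain

1. **log2 transform** of raw intensities (zero intensities are treated as
   not identified).
2. **Quantile normalization** with missing values. The reference
   distribution is the mean across samples of each sample's observed
   quantile function, evaluated on a common grid with linear interpolation
   where observed counts differ; each observed value is replaced by the
   reference quantile at its within-sample rank (average rank for ties;
   ranks computed over observed values only; missing cells stay missing).
   For complete matrices this reduces to the classic mean-of-sorted-columns
   algorithm and is cross-checked against `limma::normalizeQuantiles` in the
   test suite. Ties spanning more than two ranks are interpolated at the
   mean rank position rather than averaging the reference values
   themselves; the two differ only when the reference is locally nonlinear.
3. **Gene collapse**: per (gene, sample), the mean of that gene's protein
   isoforms' *observed* values. Treating missing isoform values as zero
   would fabricate signal on the log scale; a gene missing in all isoforms
   stays missing. Proteins without a gene symbol remain available at the
   protein level but are excluded from the gene matrix.
4. **Missingness policies.** Differential analyses use genes with
   missing fraction < 0.5 over all samples, with no imputation, so every
   test sees real measurements only. Biomarker screening uses genes with
   missing fraction < 0.7 over tumors (or over stage-I tumors for the
   diagnostic screen) and fills every remaining gap with the global minimum
   observed value of the gene-level matrix: absence in non-tumor tissue is
   exactly the signal a tumor marker screen wants to keep, and minimum
   imputation encodes "below detection" explicitly. Thresholds are strict —
   a gene at exactly the missingness bound is dropped. The imputation
   minimum is taken over the full gene matrix before row filtering
   (switchable to the filtered matrix).

## Detection-frequency sets

Identification fractions are computed per group on the pre-imputation
matrix (the function warns if handed an imputed one). A gene is an LRP when
identified in strictly more than 70% of tumors and strictly less than 30%
of pooled non-tumors (NAT + benign); NDRP is the exact mirror. The
classification depends only on the missingness pattern, so it is invariant
to any monotone transform of the abundances — a property test in the suite.

## Differential expression

Two-sided Wilcoxon rank-sum per gene on observed values, with fold change
defined as the ratio of group medians: since the median commutes with
monotone transforms, `2^(median_a − median_b)` on log2 data equals the
ratio of raw-intensity medians. Exact enumeration is used for tie-free
samples up to a combined n of 16; beyond that the normal approximation with
tie and continuity corrections applies (its worst-case two-sided error at
8 + 8 is 0.011, which is why small samples take the exact path; at the
cohort sizes the screens use, the error is far below 0.01). Identical
constant groups give p = 1 by convention. Genes with fewer than 3 observed
values in either group keep their fold change but are not tested.
Benjamini–Hochberg correction is applied over the tested genes.

**MNAR truncation bias.** When detection offsets differ between groups, the
*observed* values of a gene are differently truncated: a gene detected in
only the upper tail of the non-tumor distribution has an inflated non-tumor
median, so its apparent fold change shrinks. Two consequences are worth
knowing. First, null calibration of the observed-value Wilcoxon chain is
only exact when detection offsets are equal across groups — with unequal
offsets even a gene with no true group effect shows distributional
differences among its observed values. That is a property of MNAR data, not
of the implementation; the calibration tests therefore use equal offsets.
Second, planted fold changes are attenuated on the unimputed matrix, which
is why the biomarker cascades (like the screening practice they model) run
their fold-change gates on the minimum-imputed matrix, where absence counts
as "low" rather than being ignored.

## Survival screening

Kaplan–Meier product-limit estimation is delegated to lifelines. The
two-group log-rank (Mantel–Cox) statistic is computed directly —
`(ΣO₁−E₁)²/ΣV` with the hypergeometric variance per event time — because
the screen needs each arm's observed/expected ratio to decide *direction*:
a gene is poor-prognosis when its high-expression arm has the larger O/E.
The implementation is verified against `lifelines.statistics.logrank_test`
and against an exact permutation oracle on small fixtures. Zero events give
χ² = 0, p = 1 by convention.

Per gene, tumor samples with an observed value are split at the median
(values equal to the median go to the low arm — deterministic and
order-independent; the split quantile is a parameter). Genes with fewer
than 4 informative samples, constant values, or a degenerate split are
skipped with an explicit reason. The 1-df χ² approximation is
anti-conservative in small cohorts: at ~50 tumors (~30 events) the realized
size at nominal 0.05 is ~0.08, falling within the 99% binomial envelope of
0.05 at the default 103-tumor scale (~65 events). Analyses on small cohorts
should prefer permutation p-values.

## Screening cascades

All cascades emit one row per gene with every filter's boolean plus the
final `candidate = AND(filters)` — the audit invariant tested on every run.
Cascades are monotone: loosening any threshold can only grow the candidate
set.

- **Prognostic**: identification in > 70% of tumors (pre-imputation) →
  abundance rank ≤ 1,000 (rank 1 = highest median log2 abundance across
  tumors on the imputed matrix; exact ties break alphabetically) → tumor vs
  non-tumor fold change > 4 with Wilcoxon p < 0.05 → poor-prognosis
  log-rank p < 0.05. The three-filter prefilter subset is reported
  separately. If no tumor carries the endpoint, the cascade stops after the
  prefilter with `attrs["survival_status"] = "unavailable"`.
- **Diagnostic**: the stage-I analogue — detection in > 70% of stage-I
  tumors, top-1,000 abundance among stage-I tumors, *at least* fourfold
  (≥ 4, the boundary differs deliberately from the prognostic screen's
  strict > 4) higher in stage I than in NAT with BH q < 0.05, and membership
  in a secretome gene set (serum-measurable candidates). The comparator is
  NAT only, not pooled non-tumor.
- **Stage partition**: up-regulation (fold > 2, p < 0.05) in the
  stage-I-vs-non-tumor and entire-cohort-vs-non-tumor contrasts classifies
  genes as shared, stage-I-unique, entire-unique, or shared-down.
- **Gradual trend**: strictly monotone group medians across non-tumor →
  stage I → stage II–IV with both adjacent two-sided Wilcoxon tests at
  p < 0.05. "Gradual" has no canonical definition; this operationalization
  (monotone medians + two adjacent tests) is deliberate and its false-positive
  rate is bounded by p² under independence, which the suite verifies.

## Gene-dependency annotation

Median CERES score per gene over a user-supplied cell-line panel (the panel
is an input, not a constant), `dependent` when the median is below −0.6
(parameterizable). Joined onto screen results by a row-preserving left
join. Both the DepMap CSV layout (cell lines × "SYMBOL (entrez)") and a
generic genes × cell-lines TSV are accepted, auto-detected from the header.

## Synthetic cohort generator

Per protein p, baseline `b_p ~ N(25, 2.5²)` log2 units; per sample s in
group g, true abundance `x_ps = b_p + Δ(gene, group, stage) + ε`,
`ε ~ N(0, 1.2²)`. Detection is MNAR-logistic: a cell is observed with
probability `σ(slope · (x − (τ + offset_g)))`, defaults τ = 24.8, slope = 1,
offsets −1.0 / 0.0 / +0.15 for tumor / NAT / benign. These values come from
a closed-form Gaussian-logistic calculation so the expected identified-gene
counts per sample sit near 7,400 / 5,900 / 5,700 for tumor / NAT / benign
out of 11,234 genes — tumors identify more proteins, as tissue cohorts of
this design report. Default scale: 103 tumor/NAT pairs + 14 benign = 220
samples, 11,726 proteins collapsing to 11,234 unique genes (492 extra
isoforms assigned to random genes). Stage and subtype compositions are
fixed by largest-remainder apportionment of the configured proportions
(51/103 stage I; subtype proportions 0.48/0.18/0.21/0.05/0.08 for
ACI/PAP/SOL/LEP/MIX) and randomly assigned to patients — a study cohort has
a fixed composition, not an iid-sampled one.

Planted effects (all disjoint gene sets):

- **Differential**: tumor-wide log2 shifts drawn from (2, 4) by default,
  30 genes, 30% negated.
- **Prognostic**: genes carrying both a tumor-elevation boost (3.0 log2 —
  the prognostic cascade only ever reports tumor-elevated genes, so an
  unelevated "prognostic" gene could never be a candidate) and a hazard
  link: tumor hazard `h = h₀ · exp(Σ coef · ε_gs)` with coef = 0.8 per log2
  unit over the patient-specific deviation ε of the gene from its
  structural expectation. Keying the hazard to ε rather than to the raw
  abundance keeps h₀ meaningful: the gene's random baseline and the
  tumor-wide boost shift all patients equally and would otherwise rescale
  the cohort's hazard by exp(±several units). Event times are exponential
  with h₀ = 0.0173/month (median ~40 months at baseline), independent
  exponential censoring calibrated to a 35% censoring fraction, and an
  administrative follow-up cap at 120 months. DFS uses a 0.4·h recurrence
  hazard combined with death.
- **Stage trend**: +1.0 log2 per stratum (non-tumor 0, stage I 1,
  stage II–IV 2) — one doubling per stratum, the magnitude a trend screen
  is meant to catch.
- **Stage-I-unique**: +1.5 log2 in stage-I tumors only. This is moderate by
  design: with early-stage tumors ~half the cohort, the entire-cohort
  median of an early-only boost b moves by roughly 0.57·b (mixture median,
  detection-weighted), so a boost must satisfy both 2^b > 2 (up in the
  early contrast) and 2^(0.57·b) < 2 (not up in the entire contrast) to be
  *well-posed* as early-unique. The admissible window is narrower than the
  gene-to-gene spread of the MNAR truncation bias (~±0.25 log2), so no
  boost makes recovery near-perfect: measured stage-I-unique sensitivity is
  ~0.6–0.8 at this prevalence. That ceiling is a genuine property of
  median-fold-change partitioning at balanced prevalence, not an
  implementation artifact, and it is why the recovery test asserts a
  conservative bound (≥ 0.5) rather than a high one.

Same config + seed gives bit-identical output (`numpy.default_rng`).

**What the generator does not emulate**: batch effects, peptide-to-protein
roll-up noise, heteroscedastic group variances, correlated gene modules,
real pathway structure, or the breadth of genuinely tumor-specific biology
(the default cohort plants ~75 affected genes, so frequency-set and
candidate counts are far smaller than a real cohort's). Passing tests
demonstrate that each statistical stage does what it claims on data with
the assumed structure — not that the thresholds are optimal for any
particular real cohort.

## Recovery scoring

`truth_recovery_report` excludes a planted gene from the sensitivity
denominator when it is missing in more than 30% of tumor samples: the
screens restrict themselves to well-detected proteins, so an effect the
instrument cannot see is not a recoverable effect. Specificity counts
unplanted genes left unflagged.

## Numerical conventions

- All screening thresholds use strict inequalities exactly as named
  ("more than 70%", "> 4-fold", "at least fourfold" ≥ 4).
- Abundance-rank ties break alphabetically by gene symbol (determinism).
- Median-split ties go to the low arm.
- p-values of 1 are returned (not NaN) for degenerate tests; skipped genes
  carry NaN p and an explicit skip reason.
- BH adjustment passes NaN (untested) entries through without counting them
  as hypotheses.

## Pipeline problem sizes

The bundled acceptance script runs the full chain once at the default
220-sample / 11,726-protein scale (~1 minute on one CPU) and the recovery
simulations at 50–100 pairs × 400–800 proteins over 10–12 seeds; the test
suite uses 25–103 pairs × 300–1,200 proteins, chosen so each statistical
claim is tested at the smallest scale where it is stable.
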