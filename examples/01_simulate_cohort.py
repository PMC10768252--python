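"""Generate a synthetic LUAD proteome cohort and inspect its structure.

The generator emulates a label-free tissue study: paired tumor/NAT samples
plus a benign-disease group, log2 intensities with abundance-dependent
(MNAR) dropout, and a ground-truth manifest of every planted effect.
"""

from luadproteo import CohortConfig, generate_cohort, select_samples

cfg = CohortConfig(n_patients_paired=40, n_benign=6, n_proteins=2000, n_extra_isoforms=80, seed=7)
matrix, ann, truth = generate_cohort(cfg)

print(f"matrix: {matrix.values.shape[0]} proteins x {matrix.values.shape[1]} samples")
print(f"missing cells: {matrix.n_missing} ({matrix.values.isna().mean().mean():.1%})")

per_sample = matrix.values.notna().sum(axis=0)
for group in ("tumor", "nat", "benign"):
    ids = select_samples(ann, group)
    print(f"mean proteins identified per {group:6s} sample: {per_sample[ids].mean():7.1f}")

print(f"planted effects: {len(truth.de_genes)} differential, "
      f"{len(truth.prognostic_genes)} prognostic, "
      f"{len(truth.stage_trend_genes)} stage-trend, "
      f"{len(truth.stage1_unique_genes)} stage-I-unique")
# Tumors identify more proteins than NAT/benign because the detection
# threshold is lower in tumors - the MNAR structure the analysis must handle.
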