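"""Matrix normalization: log2 transform, NA-tolerant quantile normalization,
gene-level collapse, and the two missingness policies.

The processing order mirrors standard label-free practice: raw intensities
are log2 transformed, all samples are quantile normalized onto a shared
reference distribution, protein rows are collapsed to gene symbols by the
mean of observed isoform values, and a missingness policy then either drops
poorly observed genes (differential-expression setting) or additionally
imputes remaining gaps with the global matrix minimum (biomarker-screening
setting, where absence in non-tumor tissue is itself the signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (
    GeneQuantMatrix,
    ProteinQuantMatrix,
    SCALE_LOG2,
    SCALE_QN,
    SCALE_RAW,
    select_samples,
)

POLICY_SCOPES = ("all_samples", "tumor_samples", "early_stage_tumor_samples")


@dataclass(frozen=True)
class MissingPolicy:
    """Row-filtering (and optional minimum-value imputation) policy.

    mode 'drop_rows' keeps genes whose missing fraction within ``scope`` is
    strictly below ``max_missing_fraction`` and leaves gaps untouched;
    'impute_min' additionally fills every remaining gap (in all samples)
    with the global minimum observed value.
    """

    mode: str  # 'drop_rows' | 'impute_min'
    max_missing_fraction: float
    scope: str = "all_samples"

    def __post_init__(self) -> None:
        if self.mode not in ("drop_rows", "impute_min"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if not 0 < self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in (0, 1]")
        if self.scope not in POLICY_SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}; allowed: {POLICY_SCOPES}")


#: differential-expression setting: <50% missing over all samples, no imputation
DE_POLICY = MissingPolicy(mode="drop_rows", max_missing_fraction=0.5, scope="all_samples")
#: prognostic-biomarker setting: <70% missing over tumors, minimum-value imputation
BIOMARKER_POLICY = MissingPolicy(mode="impute_min", max_missing_fraction=0.7, scope="tumor_samples")
#: diagnostic setting: <70% missing over stage-I tumors, minimum-value imputation
DIAGNOSTIC_POLICY = MissingPolicy(
    mode="impute_min", max_missing_fraction=0.7, scope="early_stage_tumor_samples"
)

NAMED_POLICIES = {
    "paper_de": DE_POLICY,
    "paper_biomarker": BIOMARKER_POLICY,
    "paper_diagnostic": DIAGNOSTIC_POLICY,
}


def log2_transform(m: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """log2 every observed intensity; missing cells stay missing."""
    if m.scale_tag != SCALE_RAW:
        raise ValueError(f"expected a raw-scale matrix, got {m.scale_tag!r}")
    bad = m.values <= 0
    if bad.any().any():
        prot = m.values.index[bad.any(axis=1)][0]
        samp = m.values.columns[bad.loc[prot].fillna(False)][0]
        raise ValueError(f"nonpositive intensity at protein {prot!r}, sample {samp!r}")
    return ProteinQuantMatrix(values=np.log2(m.values), gene_names=m.gene_names, scale_tag=SCALE_LOG2)


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=0)
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if (n_obs < 2).any():
        sid = df.columns[np.argmax(n_obs < 2)]
        raise ValueError(f"sample {sid!r} has fewer than 2 observed values")
    # reference = mean across samples of each sample's observed quantile
    # function, evaluated on a common grid and linearly interpolated where
    # observed counts differ
    grid = np.linspace(0.0, 1.0, int(n_obs.max()))
    ref = np.zeros_like(grid)
    for j in range(vals.shape[1]):
        col = np.sort(vals[~np.isnan(vals[:, j]), j])
        pos = np.linspace(0.0, 1.0, col.size)
        ref += np.interp(grid, pos, col)
    ref /= vals.shape[1]
    out = np.full_like(vals, np.nan)
    for j in range(vals.shape[1]):
        mask = ~np.isnan(vals[:, j])
        ranks = rankdata(vals[mask, j], method="average")  # ties share mean rank
        out[mask, j] = np.interp((ranks - 1.0) / (mask.sum() - 1.0), grid, ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(m: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Quantile normalize all samples onto the mean-quantile reference.

    Missing cells are ignored when ranking and stay missing afterwards; a
    value's replacement is the reference quantile at its within-sample rank
    (average rank for ties).  For complete matrices this is the classic
    mean-of-sorted-columns algorithm.
    """
    if m.scale_tag != SCALE_LOG2:
        raise ValueError(f"expected a log2-scale matrix, got {m.scale_tag!r}")
    return ProteinQuantMatrix(
        values=_quantile_normalize_frame(m.values), gene_names=m.gene_names, scale_tag=SCALE_QN
    )


def collapse_to_gene_level(m: ProteinQuantMatrix) -> GeneQuantMatrix:
    """Mean of observed isoform values per (gene, sample); proteins without a
    gene symbol are excluded; a gene missing in every isoform stays missing."""
    mapped = m.gene_names.notna()
    if not mapped.any():
        raise ValueError("no protein has a gene name; cannot collapse")
    vals = m.values.loc[mapped.to_numpy()]
    genes = m.gene_names[mapped].astype(str)
    collapsed = vals.groupby(genes.to_numpy()).mean()  # skips NaN; all-NaN -> NaN
    collapsed.index.name = "gene_name"
    return GeneQuantMatrix(values=collapsed, scale_tag=m.scale_tag, imputed=False)


def _scope_samples(ann: pd.DataFrame, scope: str) -> list[str]:
    if scope == "all_samples":
        return list(ann.index)
    if scope == "tumor_samples":
        return select_samples(ann, "tumor")
    if scope == "early_stage_tumor_samples":
        return select_samples(ann, "stage1")
    raise ValueError(f"unknown scope {scope!r}")


def apply_missing_policy(
    g: GeneQuantMatrix,
    ann: pd.DataFrame,
    policy: MissingPolicy,
    min_source: str = "full_matrix",
) -> GeneQuantMatrix:
    """Drop genes missing in >= max_missing_fraction of the scope samples;
    under 'impute_min', fill every remaining gap with the global minimum
    observed value.

    ``min_source`` selects whether that minimum is taken over the full
    gene-level matrix before row filtering ('full_matrix', default) or over
    the filtered matrix ('filtered_matrix').
    """
    scope_ids = [s for s in _scope_samples(ann, policy.scope) if s in g.values.columns]
    if not scope_ids:
        raise ValueError(f"policy scope {policy.scope!r} matches no samples in the matrix")
    if min_source not in ("full_matrix", "filtered_matrix"):
        raise ValueError(f"unknown min_source {min_source!r}")
    miss_frac = g.values[scope_ids].isna().mean(axis=1)
    kept = g.values.loc[miss_frac < policy.max_missing_fraction]
    if policy.mode == "drop_rows":
        return GeneQuantMatrix(values=kept.copy(), scale_tag=g.scale_tag, imputed=False)
    source = g.values if min_source == "full_matrix" else kept
    global_min = source.min().min()
    if pd.isna(global_min):
        raise ValueError("matrix has no observed values; cannot impute")
    return GeneQuantMatrix(values=kept.fillna(global_min), scale_tag=g.scale_tag, imputed=True)


def normalize_protein_matrix(m: ProteinQuantMatrix) -> GeneQuantMatrix:
    """Convenience chain: (log2 if raw) -> quantile normalize -> gene collapse."""
    if m.scale_tag == SCALE_RAW:
        m = log2_transform(m)
    if m.scale_tag == SCALE_LOG2:
        m = quantile_normalize(m)
    return collapse_to_gene_level(m)
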