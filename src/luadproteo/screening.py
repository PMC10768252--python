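"""Biomarker filtering cascades.

Four screens, each a conjunction of simple gene-level filters whose full
boolean trail is emitted per gene so the final candidate list can be
audited filter by filter:

* prognostic screen  — well-detected in tumors, high abundance, strongly
  tumor-elevated, and associated with poor survival;
* diagnostic screen  — the early-stage (stage I) analogue, FDR-corrected
  and restricted to secreted proteins (serum-measurable candidates);
* stage partition    — up-regulation shared between early-stage and entire
  tumor cohorts vs unique to one of them;
* gradual stage trend — genes whose group medians move monotonically from
  non-tumor through stage I to stage II-IV with both adjacent two-group
  tests significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import differential_table, wilcoxon_rank_sum
from .frequency import identification_fraction
from .io import GeneQuantMatrix, GeneSet, select_samples
from .normalize import BIOMARKER_POLICY, DIAGNOSTIC_POLICY, MissingPolicy, apply_missing_policy
from .survival import prognostic_association

STAGE_CLASSES = ("shared_up", "stage1_unique_up", "entire_unique_up", "shared_down", "none")


def abundance_rank(g: GeneQuantMatrix, ann: pd.DataFrame, scope="tumor", stat: str = "median") -> pd.Series:
    """Rank genes by abundance over the scope samples; rank 1 = most abundant.

    The ranking statistic is the median (or mean) log2 abundance across the
    scope samples of the imputed matrix; exact ties are broken
    alphabetically by gene name so ranks are deterministic.
    """
    ids = [s for s in select_samples(ann, scope) if s in g.values.columns]
    if not ids:
        raise ValueError("abundance rank scope matches no samples in the matrix")
    if stat == "median":
        level = g.values[ids].median(axis=1)
    elif stat == "mean":
        level = g.values[ids].mean(axis=1)
    else:
        raise ValueError(f"unknown ranking statistic {stat!r}")
    order = (
        pd.DataFrame({"level": level, "gene": level.index.astype(str)})
        .sort_values(["level", "gene"], ascending=[False, True], kind="mergesort")
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index, name="abundance_rank")
    return ranks.reindex(g.values.index)


def prognostic_screen(
    g_pre: GeneQuantMatrix,
    ann: pd.DataFrame,
    detect_frac: float = 0.7,
    top_n: int = 1000,
    fc_cut: float = 4.0,
    p_cut: float = 0.05,
    logrank_p_cut: float = 0.05,
    endpoint: str = "OS",
    comparator="nontumor",
    policy: MissingPolicy = BIOMARKER_POLICY,
) -> pd.DataFrame:
    """Prognostic biomarker cascade on a pre-imputation gene matrix.

    F1 detect_freq: identified in > detect_frac of tumor samples (on the
        pre-imputation matrix);
    F2 top_abundance: abundance rank <= top_n among tumor samples (on the
        min-imputed matrix);
    F3 de_pass: tumor vs comparator fold change > fc_cut and Wilcoxon
        p < p_cut (strict fourfold boundary);
    F4 prognostic_pass: median-split log-rank p < logrank_p_cut with the
        high-expression arm showing poor prognosis.

    candidate = F1 & F2 & F3 & F4; ``prefilter`` reports F1 & F2 & F3.  If no
    tumor sample carries the endpoint, F4/candidate are NA and
    ``result.attrs['survival_status'] == 'unavailable'``.
    """
    if g_pre.imputed:
        raise ValueError("prognostic_screen needs the pre-imputation matrix")
    freq = identification_fraction(g_pre, ann)
    f1 = freq["tumor"] > detect_frac

    imputed = apply_missing_policy(g_pre, ann, policy)
    ranks = abundance_rank(imputed, ann, scope="tumor")
    f2 = (ranks <= top_n).reindex(g_pre.gene_names, fill_value=False)

    de = differential_table(imputed, ann, ("tumor", comparator), fc_cut=fc_cut, p_cut=p_cut)
    f3_imp = (de["fold_change"] > fc_cut) & (de["p_value"] < p_cut)
    f3 = f3_imp.reindex(g_pre.gene_names, fill_value=False)

    tcol = "os_time" if endpoint == "OS" else "dfs_time"
    have_survival = ann.loc[ann["group"] == "TUMOR", tcol].notna().any()

    out = pd.DataFrame(index=g_pre.gene_names.copy())
    out.index.name = "gene"
    out["frac_tumor"] = freq["tumor"]
    out["abundance_rank"] = ranks.reindex(out.index)
    out["fold_change"] = de["fold_change"].reindex(out.index)
    out["p_value"] = de["p_value"].reindex(out.index)
    out["detect_freq"] = f1
    out["top_abundance"] = f2
    out["de_pass"] = f3
    out["prefilter"] = f1 & f2 & f3

    if have_survival:
        prog = prognostic_association(imputed, ann, endpoint=endpoint, p_cut=logrank_p_cut)
        f4_imp = prog["significant"] & (prog["direction"] == "poor")
        out["logrank_p"] = prog["p_value"].reindex(out.index)
        out["direction"] = prog["direction"].reindex(out.index)
        out["prognostic_pass"] = f4_imp.reindex(out.index, fill_value=False)
        out["candidate"] = out["prefilter"] & out["prognostic_pass"]
        out.attrs["survival_status"] = "ok"
    else:
        out["logrank_p"] = np.nan
        out["direction"] = ""
        out["prognostic_pass"] = pd.NA
        out["candidate"] = pd.NA
        out.attrs["survival_status"] = "unavailable"
    return out


def diagnostic_screen(
    g_pre: GeneQuantMatrix,
    ann: pd.DataFrame,
    secretome: GeneSet,
    detect_frac: float = 0.7,
    top_n: int = 1000,
    fc_cut: float = 4.0,
    q_cut: float = 0.05,
    comparator="nat",
    policy: MissingPolicy = DIAGNOSTIC_POLICY,
) -> pd.DataFrame:
    """Early-stage diagnostic cascade on a pre-imputation gene matrix.

    D1 detect_freq: identified in > detect_frac of stage-I tumors;
    D2 top_abundance: abundance rank <= top_n among stage-I tumors (imputed);
    D3 de_pass: stage I vs adjacent tissue fold change >= fc_cut ("at least
        fourfold") with BH q < q_cut;
    D4 secreted: gene belongs to the secretome set.
    """
    if g_pre.imputed:
        raise ValueError("diagnostic_screen needs the pre-imputation matrix")
    stage1 = select_samples(ann, "stage1")  # raises if no stage-I samples
    freq = identification_fraction(g_pre, ann, {"stage1": stage1})
    d1 = freq["stage1"] > detect_frac

    imputed = apply_missing_policy(g_pre, ann, policy)
    ranks = abundance_rank(imputed, ann, scope="stage1")
    d2 = (ranks <= top_n).reindex(g_pre.gene_names, fill_value=False)

    de = differential_table(imputed, ann, ("stage1", comparator), fc_cut=fc_cut, p_cut=q_cut, use_fdr=True)
    d3_imp = (de["fold_change"] >= fc_cut) & (de["q_value"] < q_cut)
    d3 = d3_imp.reindex(g_pre.gene_names, fill_value=False)
    d4 = pd.Series([g in secretome for g in g_pre.gene_names], index=g_pre.gene_names)

    out = pd.DataFrame(index=g_pre.gene_names.copy())
    out.index.name = "gene"
    out["frac_stage1"] = freq["stage1"]
    out["abundance_rank"] = ranks.reindex(out.index)
    out["fold_change"] = de["fold_change"].reindex(out.index)
    out["q_value"] = de["q_value"].reindex(out.index)
    out["detect_freq"] = d1
    out["top_abundance"] = d2
    out["de_pass"] = d3
    out["secreted"] = d4
    out["candidate"] = d1 & d2 & d3 & d4
    return out


def stage_partition(
    g: GeneQuantMatrix,
    ann: pd.DataFrame,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Classify genes by up-regulation in early-stage vs entire tumor cohorts.

    Both contrasts are against the pooled non-tumor samples:
    shared_up         — up in both;
    stage1_unique_up  — up only in the stage-I contrast;
    entire_unique_up  — up only in the entire-cohort contrast;
    shared_down       — down in both; none otherwise.
    """
    early = differential_table(g, ann, ("stage1", "nontumor"), fc_cut=fc_cut, p_cut=p_cut)
    entire = differential_table(g, ann, ("tumor", "nontumor"), fc_cut=fc_cut, p_cut=p_cut)
    cls = pd.Series("none", index=g.values.index, name="class")
    cls[early["up"] & entire["up"]] = "shared_up"
    cls[early["up"] & ~entire["up"]] = "stage1_unique_up"
    cls[~early["up"] & entire["up"]] = "entire_unique_up"
    cls[early["down"] & entire["down"]] = "shared_down"
    out = pd.DataFrame(
        {
            "class": cls,
            "fc_early": early["fold_change"],
            "p_early": early["p_value"],
            "fc_entire": entire["fold_change"],
            "p_entire": entire["p_value"],
        }
    )
    out.index.name = "gene"
    return out


def gradual_trend_screen(
    g: GeneQuantMatrix,
    ann: pd.DataFrame,
    p_cut: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Genes altered gradually along tumor stage.

    Three ordered strata: non-tumor, stage I, stage II/III/IV.  gradual_up
    requires strictly increasing stratum medians and two-sided Wilcoxon
    p < p_cut for both adjacent comparisons; gradual_down mirrors.
    Tumors of unknown stage are excluded.
    """
    strata = {
        "nontumor": select_samples(ann, "nontumor"),
        "stage1": select_samples(ann, "stage1"),
        "late": select_samples(ann, "late"),
    }
    arrays = {}
    for name, ids in strata.items():
        ids = [s for s in ids if s in g.values.columns]
        if not ids:
            raise ValueError(f"stratum {name!r} matches no samples in the matrix")
        arrays[name] = g.values[ids].to_numpy(dtype=float)

    rows = []
    for i, gene in enumerate(g.values.index):
        obs = {k: a[i][~np.isnan(a[i])] for k, a in arrays.items()}
        if any(v.size < min_n for v in obs.values()):
            rows.append((gene, "none", np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        m0, m1, m2 = (float(np.median(obs[k])) for k in ("nontumor", "stage1", "late"))
        p01 = wilcoxon_rank_sum(obs["nontumor"], obs["stage1"])
        p12 = wilcoxon_rank_sum(obs["stage1"], obs["late"])
        sig = p01 < p_cut and p12 < p_cut
        if m0 < m1 < m2 and sig:
            cls = "gradual_up"
        elif m0 > m1 > m2 and sig:
            cls = "gradual_down"
        else:
            cls = "none"
        rows.append((gene, cls, m0, m1, m2, p01, p12))
    out = pd.DataFrame(
        rows,
        columns=["gene", "class", "median_nontumor", "median_stage1", "median_late", "p_adjacent1", "p_adjacent2"],
    ).set_index("gene")
    return out
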