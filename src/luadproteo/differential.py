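"""Differential expression: Wilcoxon rank-sum tests, median-ratio fold
changes, and Benjamini-Hochberg correction.

The fold change of a gene is the ratio of its group medians.  On the log2
scale this is ``2**(median(a) - median(b))`` — the median commutes with any
monotone transform, so this equals the ratio of raw-intensity medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import GeneQuantMatrix, select_samples

#: up to this combined size (and with no ties) the exact null distribution is
#: used; beyond it the continuity-corrected normal approximation is accurate
#: to well under 0.01 (at 8v8 the approximation's worst-case error is 0.011,
#: so small samples must take the exact path)
EXACT_MAX_N = 16


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when n_a + n_b <= 16 and the pooled values are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Two identical constant groups give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def median_fold_change(a, b) -> tuple[float, float]:
    """(log2 fold change, fold change) from log2-scale group medians."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    log2fc = float(np.median(a) - np.median(b))
    return log2fc, float(2.0 ** log2fc)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    NaN entries (tests that were skipped) are passed through as NaN and do
    not count toward the number of hypotheses.
    """
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; selectors as accepted by io.select_samples."""

    group_a: object
    group_b: object
    name: str = ""


def differential_table(
    g: GeneQuantMatrix,
    ann: pd.DataFrame,
    contrast: tuple | Contrast,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
    use_fdr: bool = False,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-gene differential record for ``contrast`` (group A vs group B).

    Columns: median_a, median_b, log2fc, fold_change, n_a, n_b, p_value,
    q_value, up, down.  A gene with fewer than ``min_n`` observed values in
    either group keeps its fold change but gets NaN p/q and False flags.
    ``up`` means fold_change > fc_cut with (q if use_fdr else p) < p_cut;
    ``down`` mirrors with 1/fc_cut.
    """
    if isinstance(contrast, Contrast):
        sel_a, sel_b = contrast.group_a, contrast.group_b
    else:
        sel_a, sel_b = contrast
    ids_a = [s for s in select_samples(ann, sel_a) if s in g.values.columns]
    ids_b = [s for s in select_samples(ann, sel_b) if s in g.values.columns]
    if not ids_a or not ids_b:
        raise ValueError("contrast selectors must match samples present in the matrix")
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"contrast groups overlap (e.g. {sorted(overlap)[0]!r})")

    A = g.values[ids_a].to_numpy(dtype=float)
    B = g.values[ids_b].to_numpy(dtype=float)
    n = g.values.shape[0]
    med_a = np.full(n, np.nan)
    med_b = np.full(n, np.nan)
    n_a = np.zeros(n, dtype=int)
    n_b = np.zeros(n, dtype=int)
    pvals = np.full(n, np.nan)
    for i in range(n):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        n_a[i], n_b[i] = a.size, b.size
        if a.size:
            med_a[i] = np.median(a)
        if b.size:
            med_b[i] = np.median(b)
        if a.size >= min_n and b.size >= min_n:
            pvals[i] = wilcoxon_rank_sum(a, b)
    log2fc = med_a - med_b
    fc = 2.0 ** log2fc
    qvals = bh_adjust(pvals)
    stat = qvals if use_fdr else pvals
    down_cut = 1.0 / fc_cut if fc_cut > 0 else np.inf  # fc_cut 0 disables both gates
    with np.errstate(invalid="ignore"):
        up = (fc > fc_cut) & (stat < p_cut)
        down = (fc < down_cut) & (stat < p_cut)
    out = pd.DataFrame(
        {
            "median_a": med_a,
            "median_b": med_b,
            "log2fc": log2fc,
            "fold_change": fc,
            "n_a": n_a,
            "n_b": n_b,
            "p_value": pvals,
            "q_value": qvals,
            "up": up,
            "down": down,
        },
        index=g.values.index,
    )
    return out
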