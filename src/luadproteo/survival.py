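"""Kaplan-Meier estimation, log-rank testing, and per-gene median-split
prognostic screening.

The product-limit estimate comes from lifelines.  The two-group log-rank
(Mantel-Cox) statistic is computed here directly because the prognostic
screen needs each group's observed/expected event counts to call the
direction of an association (is *high* expression the poor-prognosis arm?),
which the library test does not expose; the implementation is cross-checked
against ``lifelines.statistics.logrank_test`` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2 as chi2_dist

from .io import GeneQuantMatrix, select_samples

ENDPOINTS = ("OS", "DFS")


@dataclass
class KMEstimate:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray  # ordered distinct times with >=1 event
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    n_per_group: tuple
    observed: tuple  # events per group
    expected: tuple  # expected events per group under H0

    @property
    def oe_ratio(self) -> tuple:
        return tuple(
            o / e if e > 0 else np.inf if o > 0 else np.nan
            for o, e in zip(self.observed, self.expected)
        )


def _check_times(times: np.ndarray) -> None:
    if (times <= 0).any() or not np.isfinite(times).all():
        raise ValueError("survival times must be finite and positive")


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate of the survivor function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    _check_times(times)
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    d = table["observed"].to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_.iloc[:, 0]
    survival = np.array([float(surv.loc[t]) for t in event_times])
    return KMEstimate(event_times=event_times, at_risk=at_risk, events=d, survival=survival)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test (1 df).

    chi^2 = (sum(O_a - E_a))^2 / sum(V), with the hypergeometric variance at
    each distinct event time.  Zero events overall gives chi^2 = 0, p = 1.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    _check_times(ta)
    _check_times(tb)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    obs = (float(ea.sum()), float(eb.sum()))
    n_per_group = (ta.size, tb.size)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return LogRankResult(0.0, 1.0, n_per_group, obs, (0.0, 0.0))
    o_minus_e = 0.0
    var = 0.0
    e_a = 0.0
    for t in event_times:
        at_risk = times >= t
        n1 = float(np.sum(at_risk & in_a))
        n_t = float(np.sum(at_risk))
        dead = (times == t) & (events == 1)
        d1 = float(np.sum(dead & in_a))
        d_t = float(np.sum(dead))
        e1 = d_t * n1 / n_t
        e_a += e1
        o_minus_e += d1 - e1
        if n_t > 1:
            var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    if var <= 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(chi2_dist.sf(chi2, df=1))
    expected = (e_a, obs[0] + obs[1] - e_a)
    return LogRankResult(float(chi2), p, n_per_group, obs, expected)


def median_split(values, quantile: float = 0.5) -> pd.Series:
    """Label each sample 'high' (value > split point) or 'low' (<=, ties low)."""
    values = pd.Series(values).dropna()
    if values.size < 4:
        raise ValueError("need at least 4 observed values to split")
    if values.nunique() == 1:
        raise ValueError("all values identical; no split possible")
    cut = values.quantile(quantile)
    return pd.Series(np.where(values > cut, "high", "low"), index=values.index, name="split")


def _survival_columns(endpoint: str) -> tuple[str, str]:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    return ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")


def prognostic_association(
    g: GeneQuantMatrix,
    ann: pd.DataFrame,
    endpoint: str = "OS",
    p_cut: float = 0.05,
    quantile: float = 0.5,
    min_informative: int = 4,
) -> pd.DataFrame:
    """Median-split log-rank association of every gene with survival.

    For each gene, tumor samples with an observed value are split at the
    median (ties to 'low'); the two arms are compared by log-rank.
    ``direction`` is 'poor' when the high-expression arm has the larger
    observed/expected event ratio.  Columns: chi_square, p_value, direction,
    n_high, n_low, significant, skip_reason.
    """
    tcol, ecol = _survival_columns(endpoint)
    tumors = ann.loc[select_samples(ann, "tumor")]
    tumors = tumors[tumors[tcol].notna() & tumors[ecol].notna()]
    usable = [s for s in tumors.index if s in g.values.columns]
    if not usable:
        raise ValueError(f"no tumor samples with {endpoint} survival data in the matrix")
    times_all = tumors.loc[usable, tcol].to_numpy(dtype=float)
    events_all = tumors.loc[usable, ecol].to_numpy(dtype=int)
    vals = g.values[usable].to_numpy(dtype=float)

    rows = []
    for i, gene in enumerate(g.values.index):
        row = vals[i]
        mask = ~np.isnan(row)
        n_inf = int(mask.sum())
        if n_inf < min_informative:
            rows.append((gene, np.nan, np.nan, "", 0, 0, False, "too_few_samples"))
            continue
        v = row[mask]
        if np.ptp(v) == 0:
            rows.append((gene, np.nan, np.nan, "", 0, 0, False, "constant_values"))
            continue
        cut = np.quantile(v, quantile)
        high = v > cut
        if high.sum() == 0 or (~high).sum() == 0:
            rows.append((gene, np.nan, np.nan, "", 0, 0, False, "degenerate_split"))
            continue
        t = times_all[mask]
        e = events_all[mask]
        res = logrank_test(t[high], e[high], t[~high], e[~high])
        oe = res.oe_ratio
        if np.isnan(oe[0]) or np.isnan(oe[1]):
            direction = ""
        else:
            direction = "poor" if oe[0] > oe[1] else "good"
        rows.append(
            (
                gene,
                res.chi_square,
                res.p_value,
                direction,
                int(high.sum()),
                int((~high).sum()),
                bool(res.p_value < p_cut),
                "",
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "chi_square",
            "p_value",
            "direction",
            "n_high",
            "n_low",
            "significant",
            "skip_reason",
        ],
    ).set_index("gene")
    return out


def km_curve_frame(times, events, label: str = "all") -> pd.DataFrame:
    """KM curve as a tidy frame (time, survival, group) for TSV export."""
    est = km_estimate(times, events)
    return pd.DataFrame(
        {
            "time": np.concatenate([[0.0], est.event_times]),
            "survival": np.concatenate([[1.0], est.survival]),
            "group": label,
        }
    )
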