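"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the Wilcoxon oracle
enumerates the full permutation null of the rank-sum statistic, and the
log-rank permutation oracle recomputes the statistic under every relabeling
of a small fixture.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def exact_wilcoxon_p(a, b) -> float:
    """Two-sided rank-sum p by full enumeration of group labelings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n, na = pooled.size, a.size
    obs = ranks[:na].sum()
    mu = ranks.sum() * na / n
    dev = abs(obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            count += 1
    return count / total


def permutation_logrank_p(times, events, in_a, statistic) -> float:
    """Permutation p for a two-group statistic: enumerate all relabelings
    with the same group sizes; ``statistic(times_a, events_a, times_b,
    events_b)`` must return a scalar where larger = more extreme."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    in_a = np.asarray(in_a, dtype=bool)
    n, na = times.size, int(in_a.sum())
    obs = statistic(times[in_a], events[in_a], times[~in_a], events[~in_a])
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        stat = statistic(times[mask], events[mask], times[~mask], events[~mask])
        total += 1
        if stat >= obs - 1e-12:
            count += 1
    return count / total


def bh_oracle(p) -> np.ndarray:
    """Hand BH: q_i = min over the tail of p_(j) * m / j, step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
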