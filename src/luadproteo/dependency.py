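"""CERES gene-dependency summarization and annotation of screen results.

CERES scores estimate gene essentiality from CRISPR knockout screens; more
negative means a stronger fitness dependency.  A gene whose median score
across a panel of lung-adenocarcinoma cell lines falls below a threshold
(default -0.6) is flagged as a dependency — a biomarker that is also a
dependency is a potential therapeutic target.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .io import CeresTable

DEPENDENT_THRESHOLD = -0.6


def median_ceres_score(
    t: CeresTable,
    cell_line_filter: Iterable[str] | None = None,
    threshold: float = DEPENDENT_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene median CERES score over the (filtered) cell-line panel.

    Columns: median_ceres, n_cell_lines, dependent_flag (median < threshold).
    A gene with no non-missing score in the panel keeps a NaN median and a
    False flag.  An empty filter intersection is an error.
    """
    if cell_line_filter is None:
        cols = list(t.cell_line_ids)
    else:
        wanted = list(cell_line_filter)
        cols = [c for c in t.cell_line_ids if c in set(wanted)]
        if not cols:
            raise ValueError("cell-line filter has no overlap with the CERES table")
    sub = t.scores[cols]
    med = sub.median(axis=1)
    n = sub.notna().sum(axis=1)
    flag = (med < threshold).fillna(False)
    out = pd.DataFrame(
        {"median_ceres": med, "n_cell_lines": n, "dependent_flag": flag.astype(bool)}
    )
    out.index.name = "gene"
    return out


def annotate_dependency(screen: pd.DataFrame, dep: pd.DataFrame) -> pd.DataFrame:
    """Left-join dependency records onto a screen result (index = gene).

    Genes absent from the dependency table carry a missing median; the row
    count of the screen is preserved exactly.
    """
    cols = [c for c in ("median_ceres", "n_cell_lines", "dependent_flag") if c in dep.columns]
    joined = screen.join(dep[cols], how="left")
    assert len(joined) == len(screen)
    return joined
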