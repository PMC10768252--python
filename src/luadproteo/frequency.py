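"""Identification-frequency computation and LRP/NDRP classification.

In label-free proteomics, whether a protein is identified at all carries
biological information: a protein seen in most tumors but almost never in
non-tumor tissue is tumor-associated even before any abundance statistics.
Frequencies must be computed on the pre-imputation matrix — imputation
erases the missingness pattern the classification depends on.

LRP  (LUAD-related protein): identified in more than ``hi`` of tumor
samples and in less than ``lo`` of non-tumor (NAT + benign) samples.
NDRP (NAT/benign-disease-related protein): the symmetric mirror.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd

from .io import GeneQuantMatrix, ProteinQuantMatrix, select_samples

CLASS_LRP = "LRP"
CLASS_NDRP = "NDRP"
CLASS_NEITHER = "neither"


def identification_fraction(
    g: GeneQuantMatrix | ProteinQuantMatrix,
    ann: pd.DataFrame,
    group_spec: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Fraction of samples per group in which each gene was identified.

    ``group_spec`` maps a group label to a sample selector (see
    :func:`luadproteo.io.select_samples`); the default partition is
    ``{"tumor": "tumor", "nontumor": "nontumor"}``.
    Returns a genes x groups frame of fractions in [0, 1].
    """
    if getattr(g, "imputed", False):
        warnings.warn(
            "identification fractions on an imputed matrix are meaningless; "
            "use the pre-imputation matrix",
            UserWarning,
            stacklevel=2,
        )
    if group_spec is None:
        group_spec = {"tumor": "tumor", "nontumor": "nontumor"}
    out = {}
    for label, sel in group_spec.items():
        ids = select_samples(ann, sel)
        ids = [s for s in ids if s in g.values.columns]
        if not ids:
            raise ValueError(f"group {label!r} matches no samples in the matrix")
        out[label] = g.values[ids].notna().mean(axis=1)
    return pd.DataFrame(out)


def classify_related_proteins(
    freq: pd.DataFrame,
    hi: float = 0.7,
    lo: float = 0.3,
    tumor_col: str = "tumor",
    nontumor_col: str = "nontumor",
) -> pd.DataFrame:
    """Attach the LRP/NDRP class to an identification-frequency frame.

    Inequalities are strict on both sides ("more than 70% ... less than
    30%"), so a gene at exactly the threshold is 'neither'.
    """
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    for col in (tumor_col, nontumor_col):
        if col not in freq.columns:
            raise ValueError(f"frequency frame lacks column {col!r}")
    t, n = freq[tumor_col], freq[nontumor_col]
    cls = pd.Series(CLASS_NEITHER, index=freq.index, name="class")
    cls[(t > hi) & (n < lo)] = CLASS_LRP
    cls[(n > hi) & (t < lo)] = CLASS_NDRP
    out = freq.copy()
    out["class"] = cls
    return out
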