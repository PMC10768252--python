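"""Domain containers and tabular readers/writers.

All abundance matrices are pandas DataFrames (rows = proteins or genes,
columns = samples) with ``NaN`` marking a cell where the protein was not
identified in that MS run.  Written TSVs encode missing cells as ``NA``;
both ``NA`` and the empty string parse back as missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_QN = "quantile_normalized"
SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_QN)

GROUPS = ("TUMOR", "NAT", "BENIGN")
STAGES = ("I", "II", "III", "IV", "unknown")
SUBTYPES = ("ACI", "PAP", "SOL", "LEP", "MIX", "unknown")

_NA_VALUES = ["", "NA", "NaN", "nan"]
_SURVIVAL_COLS = ("os_time", "os_event", "dfs_time", "dfs_event")


@dataclass
class ProteinQuantMatrix:
    """Protein x sample abundance matrix.

    values: DataFrame indexed by protein id, columns = sample ids, NaN = missing.
    gene_names: one gene symbol per protein (NaN where the protein maps to no gene).
    scale_tag: 'raw' | 'log2' | 'quantile_normalized'.
    """

    values: pd.DataFrame
    gene_names: pd.Series
    scale_tag: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALES:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample column: {dup!r}")
        self.gene_names = self.gene_names.reindex(self.values.index)

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())


@dataclass
class GeneQuantMatrix:
    """Gene x sample abundance matrix (one row per unique gene symbol)."""

    values: pd.DataFrame
    scale_tag: str = SCALE_LOG2
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene name: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample column: {dup!r}")

    @property
    def gene_names(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CeresTable:
    """CERES gene-essentiality scores, genes x cell lines; NaN = not screened."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate gene names in CERES table")
        if self.scores.columns.has_duplicates:
            raise ValueError("duplicate cell-line ids in CERES table")

    @property
    def gene_names(self) -> pd.Index:
        return self.scores.index

    @property
    def cell_line_ids(self) -> pd.Index:
        return self.scores.columns


# ---------------------------------------------------------------------------
# matrix IO

_GENE_COL_NAMES = {"gene_name", "gene_names", "gene", "symbol"}


def _check_duplicate_header(path: Path, sep: str) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise ValueError(f"duplicate sample column: {col!r}")
        seen.add(col)


def read_quant_matrix(
    path: str | Path,
    dialect: str = "generic_tsv",
    scale_tag: str = SCALE_RAW,
    zero_as_missing: bool | None = None,
) -> ProteinQuantMatrix:
    """Read a protein quantification matrix.

    dialect 'generic_tsv': first column = protein id, optional second column
    named gene_name/gene/symbol, remaining columns = samples.
    dialect 'maxquant_protein_groups': a MaxQuant proteinGroups.txt export;
    rows flagged Reverse or Potential contaminant are dropped and per-sample
    ``Intensity <sample>`` columns are used.

    Zero intensities are treated as not-identified for raw-scale input
    (label-free software writes 0 for absent proteins); override with
    ``zero_as_missing``.
    """
    path = Path(path)
    if zero_as_missing is None:
        zero_as_missing = scale_tag == SCALE_RAW
    if dialect == "generic_tsv":
        _check_duplicate_header(path, "\t")
        df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})
        if df.empty:
            raise ValueError(f"no data rows in {path}")
        df = df.set_index(df.columns[0])
        df.index.name = "protein_id"
        if df.columns.size and df.columns[0].lower() in _GENE_COL_NAMES:
            gene_names = df.iloc[:, 0].astype("string")
            values = df.iloc[:, 1:].astype(float)
        else:
            gene_names = pd.Series(pd.NA, index=df.index, dtype="string")
            values = df.astype(float)
    elif dialect == "maxquant_protein_groups":
        _check_duplicate_header(path, "\t")
        df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype=str)
        if df.empty:
            raise ValueError(f"no data rows in {path}")
        for col in ("Reverse", "Potential contaminant"):
            if col in df.columns:
                df = df[df[col].fillna("") != "+"]
        df = df.set_index("Majority protein IDs")
        df.index.name = "protein_id"
        gene_names = (
            df["Gene names"].astype("string")
            if "Gene names" in df.columns
            else pd.Series(pd.NA, index=df.index, dtype="string")
        )
        # take only per-sample intensity columns, not the summed "Intensity"
        int_cols = [c for c in df.columns if c.startswith("Intensity ") and len(c) > len("Intensity ")]
        if not int_cols:
            raise ValueError(f"no 'Intensity <sample>' columns in {path}")
        values = df[int_cols].astype(float)
        values.columns = [c[len("Intensity "):] for c in int_cols]
        if pd.Index(values.columns).has_duplicates:
            raise ValueError("duplicate sample column after stripping 'Intensity ' prefix")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if values.empty:
        raise ValueError(f"no data rows in {path}")
    if zero_as_missing:
        values = values.mask(values == 0)
    return ProteinQuantMatrix(values=values, gene_names=gene_names, scale_tag=scale_tag)


def write_quant_matrix(m: ProteinQuantMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.insert(0, "gene_name", m.gene_names)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_gene_matrix(path: str | Path, scale_tag: str = SCALE_LOG2, imputed: bool = False) -> GeneQuantMatrix:
    path = Path(path)
    _check_duplicate_header(path, "\t")
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_name"
    return GeneQuantMatrix(values=df.astype(float), scale_tag=scale_tag, imputed=imputed)


def write_gene_matrix(g: GeneQuantMatrix, path: str | Path) -> None:
    out = g.values.copy()
    out.index.name = "gene_name"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# sample annotation

ANNOTATION_COLUMNS = (
    "group",
    "patient_id",
    "stage",
    "subtype",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a sample-annotation frame (index = sample_id)."""
    ann = ann.copy()
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    ann["group"] = ann["group"].astype(str).str.upper().str.strip()
    bad = set(ann["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"invalid group value(s) {sorted(bad)}; allowed: {list(GROUPS)}")
    for col in ("stage", "subtype"):
        if col not in ann.columns:
            ann[col] = "unknown"
        ann[col] = ann[col].fillna("unknown").astype(str).str.strip().replace("", "unknown")
    ann["stage"] = ann["stage"].str.upper().replace({"UNKNOWN": "unknown"})
    ann["subtype"] = ann["subtype"].str.upper().replace({"UNKNOWN": "unknown"})
    bad_stage = set(ann["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"invalid stage value(s) {sorted(bad_stage)}; allowed: {list(STAGES)}")
    bad_sub = set(ann["subtype"]) - set(SUBTYPES)
    if bad_sub:
        raise ValueError(f"invalid subtype value(s) {sorted(bad_sub)}; allowed: {list(SUBTYPES)}")
    nontumor = ann["group"] != "TUMOR"
    for col in ("stage", "subtype"):
        offending = ann.index[nontumor & (ann[col] != "unknown")]
        if len(offending):
            raise ValueError(f"{col} set on non-tumor sample {offending[0]!r}")
    if "patient_id" not in ann.columns:
        ann["patient_id"] = pd.NA
    ann["patient_id"] = ann["patient_id"].astype("string").replace("", pd.NA)
    for col in _SURVIVAL_COLS:
        if col not in ann.columns:
            ann[col] = np.nan
        ann[col] = pd.to_numeric(ann[col], errors="coerce")
        offending = ann.index[nontumor & ann[col].notna()]
        if len(offending):
            raise ValueError(f"survival column {col} set on non-tumor sample {offending[0]!r}")
    for col in ("os_time", "dfs_time"):
        if (ann[col].dropna() < 0).any():
            raise ValueError(f"negative {col}")
    for col in ("os_event", "dfs_event"):
        vals = set(ann[col].dropna().unique())
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be 0/1, got {sorted(vals)}")
    # pairing: at most one TUMOR and one NAT per patient_id, no pairing for BENIGN
    paired = ann[ann["patient_id"].notna()]
    if (paired["group"] == "BENIGN").any():
        sid = paired.index[paired["group"] == "BENIGN"][0]
        raise ValueError(f"patient_id set on BENIGN sample {sid!r}")
    for grp in ("TUMOR", "NAT"):
        counts = paired.loc[paired["group"] == grp, "patient_id"].value_counts()
        if (counts > 1).any():
            pid = counts.index[counts > 1][0]
            raise ValueError(f"patient {pid!r} has more than one {grp} sample")
    return ann[list(ANNOTATION_COLUMNS)]


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-sample annotation TSV; returns a frame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("annotation needs columns 'sample_id' and 'group'")
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    df = df.set_index("sample_id")
    return validate_annotation(df)


def write_sample_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def annotation_from_sample_names(sample_ids: Iterable[str]) -> pd.DataFrame:
    """Convenience for supplementary-style matrices whose column names encode
    the group: suffix 'T' -> TUMOR, suffix 'N' -> NAT, containing 'benign'
    (case-insensitive) -> BENIGN.  Explicit annotation files are preferred."""
    rows = []
    for sid in sample_ids:
        low = sid.lower()
        if "benign" in low:
            grp, pid = "BENIGN", pd.NA
        elif sid.endswith("T"):
            grp, pid = "TUMOR", sid[:-1]
        elif sid.endswith("N"):
            grp, pid = "NAT", sid[:-1]
        else:
            raise ValueError(f"cannot infer group from sample name {sid!r}")
        rows.append((sid, grp, pid))
    ann = pd.DataFrame(rows, columns=["sample_id", "group", "patient_id"]).set_index("sample_id")
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# gene sets and CERES tables

def read_gene_set(path: str | Path, name: str) -> GeneSet:
    symbols = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                symbols.append(sym)
    if not symbols:
        raise ValueError(f"empty gene set file {path}")
    return GeneSet(name=name, members=frozenset(symbols))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(gs.members):
            fh.write(sym + "\n")


_DEPMAP_GENE_RE = re.compile(r"^(.+) \(\d+\)$")


def read_ceres_table(path: str | Path) -> CeresTable:
    """Read CERES scores from either the generic genes x cell-lines TSV or the
    DepMap CSV export (cell lines on rows, columns 'SYMBOL (entrez)'); the
    layout is auto-detected from the header."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})
    if df.empty:
        raise ValueError(f"empty CERES file {path}")
    df = df.set_index(df.columns[0])
    depmap_like = sum(bool(_DEPMAP_GENE_RE.match(c)) for c in df.columns) > len(df.columns) / 2
    if depmap_like:
        df.columns = [_DEPMAP_GENE_RE.match(c).group(1) if _DEPMAP_GENE_RE.match(c) else c for c in df.columns]
        df = df.astype(float).T  # -> genes x cell lines
        df = df.loc[~df.index.duplicated()]
    else:
        df = df.astype(float)
    df.index.name = "gene_name"
    return CeresTable(scores=df)


def write_ceres_table(t: CeresTable, path: str | Path) -> None:
    out = t.scores.copy()
    out.index.name = "gene_name"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# sample selectors

def select_samples(ann: pd.DataFrame, sel) -> list[str]:
    """Resolve a selector to a list of sample ids.

    Named selectors (case-insensitive): tumor, nat, benign,
    nontumor (NAT + benign pooled), stage1/early (stage-I tumors),
    late (stage II/III/IV tumors), sol, nonsol (all non-SOL tumors,
    including tumors without subtype information).
    A list/array of sample ids passes through after validation.
    """
    if not isinstance(sel, str):
        ids = list(sel)
        missing = [s for s in ids if s not in ann.index]
        if missing:
            raise ValueError(f"unknown sample id(s): {missing[:3]}")
        return ids
    key = sel.lower().replace("-", "_").replace(" ", "_")
    g = ann["group"]
    if key == "tumor":
        mask = g == "TUMOR"
    elif key == "nat":
        mask = g == "NAT"
    elif key == "benign":
        mask = g == "BENIGN"
    elif key in ("nontumor", "non_tumor"):
        mask = g != "TUMOR"
    elif key in ("stage1", "stage_i", "early", "early_stage"):
        mask = (g == "TUMOR") & (ann["stage"] == "I")
    elif key in ("late", "late_stage", "stage234"):
        mask = (g == "TUMOR") & ann["stage"].isin(["II", "III", "IV"])
    elif key == "sol":
        mask = (g == "TUMOR") & (ann["subtype"] == "SOL")
    elif key in ("nonsol", "non_sol"):
        mask = (g == "TUMOR") & (ann["subtype"] != "SOL")
    else:
        raise ValueError(f"unknown sample selector {sel!r}")
    ids = list(ann.index[mask])
    if not ids:
        raise ValueError(f"selector {sel!r} matches no samples")
    return ids
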