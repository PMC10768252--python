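import numpy as np
import pandas as pd
import pytest

from luadproteo import (
    CohortConfig,
    GeneQuantMatrix,
    ProteinQuantMatrix,
    collapse_to_gene_level,
    generate_cohort,
)
from luadproteo.io import validate_annotation


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across tests (25 pairs, 5 benign)."""
    cfg = CohortConfig(
        n_patients_paired=25,
        n_benign=5,
        n_proteins=600,
        n_extra_isoforms=25,
        n_planted_de=15,
        de_log2fc_range=(2.5, 3.5),
        de_frac_down=0.2,
        n_planted_prognostic=2,
        n_planted_stage_trend=10,
        n_planted_stage1_unique=10,
        seed=42,
    )
    matrix, ann, truth = generate_cohort(cfg)
    return cfg, matrix, ann, truth


@pytest.fixture(scope="session")
def small_gene_matrix(small_cohort):
    _, matrix, ann, _ = small_cohort
    return collapse_to_gene_level(matrix), ann


@pytest.fixture()
def tiny_ann():
    """2 tumor/NAT pairs + 1 benign, with survival on the tumors."""
    ann = pd.DataFrame(
        {
            "group": ["TUMOR", "TUMOR", "NAT", "NAT", "BENIGN"],
            "patient_id": ["p1", "p2", "p1", "p2", None],
            "stage": ["I", "II", None, None, None],
            "subtype": ["SOL", "ACI", None, None, None],
            "os_time": [12.0, 30.0, None, None, None],
            "os_event": [1, 0, None, None, None],
            "dfs_time": [10.0, 30.0, None, None, None],
            "dfs_event": [1, 0, None, None, None],
        },
        index=pd.Index(["t1", "t2", "n1", "n2", "b1"], name="sample_id"),
    )
    return validate_annotation(ann)


@pytest.fixture()
def toy_gene_matrix(tiny_ann):
    """5 genes x 5 samples with a hand-placed missing pattern."""
    vals = pd.DataFrame(
        {
            "t1": [10.0, 8.0, np.nan, 5.0, 7.0],
            "t2": [11.0, 9.0, 6.0, np.nan, 7.5],
            "n1": [6.0, np.nan, 6.5, 5.5, 7.2],
            "n2": [5.5, np.nan, 7.0, 6.0, 6.8],
            "b1": [6.2, np.nan, np.nan, 5.8, 7.1],
        },
        index=pd.Index(["GA", "GB", "GC", "GD", "GE"], name="gene_name"),
    )
    return GeneQuantMatrix(values=vals, scale_tag="log2")
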