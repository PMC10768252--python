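import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from luadproteo import (
    BIOMARKER_POLICY,
    DE_POLICY,
    MissingPolicy,
    apply_missing_policy,
    collapse_to_gene_level,
    log2_transform,
    quantile_normalize,
)
from luadproteo.io import GeneQuantMatrix, ProteinQuantMatrix, SCALE_LOG2, SCALE_QN


def _pqm(values: pd.DataFrame, genes=None, scale="log2") -> ProteinQuantMatrix:
    genes = pd.Series(genes if genes is not None else values.index, index=values.index, dtype="string")
    return ProteinQuantMatrix(values=values, gene_names=genes, scale_tag=scale)


class TestLog2Transform:
    def test_values_and_missing(self):
        vals = pd.DataFrame({"s1": [8.0, 1.0], "s2": [2.0, np.nan]}, index=["P1", "P2"])
        out = log2_transform(_pqm(vals, scale="raw"))
        assert out.values.loc["P1", "s1"] == 3.0
        assert out.values.loc["P2", "s1"] == 0.0
        assert np.isnan(out.values.loc["P2", "s2"])
        assert out.scale_tag == SCALE_LOG2

    def test_nonpositive_names_offender(self):
        vals = pd.DataFrame({"s1": [8.0], "s2": [-1.0]}, index=["P9"])
        with pytest.raises(ValueError, match="P9.*s2"):
            log2_transform(_pqm(vals, scale="raw"))


class TestQuantileNormalize:
    def test_two_complete_columns_hand_example(self):
        vals = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]}, index=list("abc"))
        out = quantile_normalize(_pqm(vals))
        expected = [2.5, 3.5, 4.5]
        assert list(out.values["s1"]) == expected
        assert list(out.values["s2"]) == expected
        assert out.scale_tag == SCALE_QN

    def test_identical_columns_are_a_fixed_point(self):
        col = [5.0, 1.0, 3.0, 2.0]
        vals = pd.DataFrame({"s1": col, "s2": col, "s3": col}, index=list("abcd"))
        out = quantile_normalize(_pqm(vals))
        pd.testing.assert_frame_equal(out.values, vals)

    def test_complete_columns_share_sorted_vector_and_total_mean(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(20, 3, size=(100, 8)), index=[f"P{i}" for i in range(100)])
        vals.columns = [f"s{j}" for j in range(8)]
        out = quantile_normalize(_pqm(vals)).values
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 8):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)
        assert np.isclose(out.to_numpy().mean(), vals.to_numpy().mean())

    def test_missing_cells_stay_missing(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(20, 3, size=(50, 5)))
        vals.columns = [f"s{j}" for j in range(5)]
        vals.index = [f"P{i}" for i in range(50)]
        mask = rng.random(vals.shape) < 0.2
        vals = vals.mask(mask)
        out = quantile_normalize(_pqm(vals)).values
        assert out.isna().equals(vals.isna())

    def test_sample_with_one_observation_errors(self):
        vals = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, np.nan]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="s2"):
            quantile_normalize(_pqm(vals))

    def test_matches_limma_on_complete_matrix(self, tmp_path):
        """Independent oracle: limma::normalizeQuantiles on a complete
        matrix (tie-free), where the algorithm is unambiguous."""
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(22, 2.5, size=(30, 5)),
                            index=[f"P{i}" for i in range(30)],
                            columns=[f"s{j}" for j in range(5)])
        ours = quantile_normalize(_pqm(vals)).values
        inp, outp = tmp_path / "in.tsv", tmp_path / "out.tsv"
        vals.to_csv(inp, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{inp}", row.names=1))
            write.table(normalizeQuantiles(m), "{outp}", sep="\\t", quote=FALSE)
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        theirs = pd.read_csv(outp, sep="\t")
        assert np.allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_property_complete_columns_equal_after_normalization(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(5, 40), rng.integers(2, 6)
        vals = pd.DataFrame(rng.normal(0, 1, size=(n, k)),
                            index=[f"P{i}" for i in range(n)],
                            columns=[f"s{j}" for j in range(k)])
        out = quantile_normalize(_pqm(vals)).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])


class TestGeneCollapse:
    def test_mean_of_observed_isoforms(self):
        vals = pd.DataFrame({"s1": [4.0, 6.0], "s2": [4.0, np.nan]}, index=["P1", "P2"])
        g = collapse_to_gene_level(_pqm(vals, genes=["GA", "GA"]))
        assert g.values.loc["GA", "s1"] == 5.0  # mean of 4 and 6
        assert g.values.loc["GA", "s2"] == 4.0  # one observed isoform
        assert g.values.shape == (1, 2)

    def test_single_protein_gene_passthrough_and_unmapped_excluded(self):
        vals = pd.DataFrame({"s1": [4.0, 9.0]}, index=["P1", "P2"])
        g = collapse_to_gene_level(_pqm(vals, genes=["GA", None]))
        assert list(g.gene_names) == ["GA"]
        assert g.values.loc["GA", "s1"] == 4.0

    def test_no_mappable_protein_errors(self):
        vals = pd.DataFrame({"s1": [4.0]}, index=["P1"])
        with pytest.raises(ValueError, match="gene name"):
            collapse_to_gene_level(_pqm(vals, genes=[None]))


class TestMissingPolicy:
    def _gene(self, values: pd.DataFrame) -> GeneQuantMatrix:
        return GeneQuantMatrix(values=values, scale_tag="log2")

    def _ann10(self):
        idx = [f"t{i}" for i in range(10)]
        return pd.DataFrame({"group": ["TUMOR"] * 10, "stage": ["I"] * 10}, index=idx)

    def test_boundary_exactly_at_threshold_is_dropped(self):
        # observed in 3 of 10 tumors -> missing fraction 0.7, not < 0.7 -> drop
        ann = self._ann10()
        row = [1.0, 2.0, 3.0] + [np.nan] * 7
        vals = pd.DataFrame([row, [1.0] * 10], index=["Gdrop", "Gkeep"], columns=ann.index, dtype=float)
        out = apply_missing_policy(self._gene(vals), ann, BIOMARKER_POLICY)
        assert list(out.gene_names) == ["Gkeep"]

    def test_impute_min_uses_global_minimum(self):
        ann = self._ann10()
        vals = pd.DataFrame(
            [[2.5] + [9.0] * 9, [5.0] * 9 + [np.nan]],
            index=["Gmin", "Ggap"], columns=ann.index, dtype=float,
        )
        out = apply_missing_policy(self._gene(vals), ann, BIOMARKER_POLICY)
        assert out.values.loc["Ggap", ann.index[-1]] == 2.5
        assert out.imputed

    def test_drop_rows_on_complete_matrix_is_identity(self, toy_gene_matrix, tiny_ann):
        complete = GeneQuantMatrix(values=toy_gene_matrix.values.dropna(), scale_tag="log2")
        out = apply_missing_policy(complete, tiny_ann, DE_POLICY)
        pd.testing.assert_frame_equal(out.values, complete.values)

    def test_imputation_never_changes_observed_values_nor_lowers_minimum(self, small_cohort):
        _, matrix, ann, _ = small_cohort
        g = collapse_to_gene_level(matrix)
        out = apply_missing_policy(g, ann, BIOMARKER_POLICY)
        pre = g.values.loc[out.gene_names]
        obs = pre.notna()
        assert np.allclose(out.values.to_numpy()[obs.to_numpy()], pre.to_numpy()[obs.to_numpy()])
        assert out.values.min().min() >= g.values.min().min() - 1e-12

    def test_collapse_then_policy_commutes_with_sample_reordering(self, small_cohort):
        _, matrix, ann, _ = small_cohort
        g1 = apply_missing_policy(collapse_to_gene_level(matrix), ann, DE_POLICY)
        perm = list(reversed(matrix.sample_ids))
        shuffled = ProteinQuantMatrix(values=matrix.values[perm], gene_names=matrix.gene_names,
                                      scale_tag=matrix.scale_tag)
        g2 = apply_missing_policy(collapse_to_gene_level(shuffled), ann, DE_POLICY)
        pd.testing.assert_frame_equal(g1.values, g2.values[g1.values.columns])

    def test_empty_scope_errors(self, toy_gene_matrix):
        nat_only = pd.DataFrame({"group": ["NAT"]}, index=["n1"])
        with pytest.raises(ValueError):
            apply_missing_policy(toy_gene_matrix, nat_only, BIOMARKER_POLICY)

    def test_policy_validation(self):
        with pytest.raises(ValueError, match="mode"):
            MissingPolicy(mode="zap", max_missing_fraction=0.5)
        with pytest.raises(ValueError, match="fraction"):
            MissingPolicy(mode="drop_rows", max_missing_fraction=0.0)
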