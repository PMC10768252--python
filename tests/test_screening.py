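import numpy as np
import pandas as pd
import pytest

from luadproteo import (
    CohortConfig,
    GeneSet,
    abundance_rank,
    apply_missing_policy,
    collapse_to_gene_level,
    diagnostic_screen,
    generate_cohort,
    gradual_trend_screen,
    prognostic_screen,
    select_samples,
    stage_partition,
)
from luadproteo.io import GeneQuantMatrix
from luadproteo.normalize import DE_POLICY


@pytest.fixture(scope="module")
def screen_cohort():
    """Cohort sized for the cascade tests (full-scale stage composition)."""
    cfg = CohortConfig(
        n_patients_paired=103, n_benign=14, n_proteins=1200, n_extra_isoforms=50,
        n_planted_de=20, de_log2fc_range=(2.5, 3.5), de_frac_down=0.0,
        n_planted_prognostic=2, n_planted_stage_trend=12, n_planted_stage1_unique=12,
        seed=17,
    )
    m, ann, truth = generate_cohort(cfg)
    g = collapse_to_gene_level(m)
    return g, ann, truth


class TestAbundanceRank:
    def _ann(self, ids):
        return pd.DataFrame({"group": ["TUMOR"] * len(ids), "stage": "I", "subtype": "unknown"}, index=ids)

    def test_rank_by_median(self):
        ids = ["t1", "t2", "t3"]
        vals = pd.DataFrame([[10.0] * 3, [8.0] * 3, [9.0] * 3], index=["GA", "GB", "GC"], columns=ids)
        ranks = abundance_rank(GeneQuantMatrix(values=vals, imputed=True), self._ann(ids))
        assert list(ranks) == [1, 3, 2]

    def test_ties_break_alphabetically(self):
        ids = ["t1", "t2"]
        vals = pd.DataFrame([[8.0] * 2, [8.0] * 2], index=["GB", "GA"], columns=ids)
        ranks = abundance_rank(GeneQuantMatrix(values=vals, imputed=True), self._ann(ids))
        assert ranks["GA"] == 1 and ranks["GB"] == 2

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(2)
        ids = [f"t{i}" for i in range(6)]
        vals = pd.DataFrame(rng.normal(20, 2, (15, 6)), index=[f"G{i}" for i in range(15)], columns=ids)
        ann = self._ann(ids)
        r1 = abundance_rank(GeneQuantMatrix(values=vals, imputed=True), ann)
        r2 = abundance_rank(GeneQuantMatrix(values=vals[list(reversed(ids))], imputed=True), ann)
        assert r1.equals(r2)


class TestPrognosticScreen:
    def test_audit_identity_and_trail_consistency(self, screen_cohort):
        g, ann, _ = screen_cohort
        res = prognostic_screen(g, ann)
        flags = res[["detect_freq", "top_abundance", "de_pass", "prognostic_pass"]].fillna(False).astype(bool)
        expected = flags.all(axis=1)
        assert (res["candidate"].fillna(False).astype(bool) == expected).all()
        assert (res["prefilter"] == flags[["detect_freq", "top_abundance", "de_pass"]].all(axis=1)).all()

    def test_cascade_monotone_in_thresholds(self, screen_cohort):
        g, ann, _ = screen_cohort
        strict = prognostic_screen(g, ann, detect_frac=0.7, top_n=500, fc_cut=4.0, p_cut=0.01)
        loose = prognostic_screen(g, ann, detect_frac=0.5, top_n=2000, fc_cut=2.0, p_cut=0.05)
        strict_set = set(strict.index[strict["candidate"].fillna(False).astype(bool)])
        loose_set = set(loose.index[loose["candidate"].fillna(False).astype(bool)])
        assert strict_set <= loose_set

    def test_degenerate_thresholds_prefilter_everything(self, screen_cohort):
        g, ann, _ = screen_cohort
        # p_cut just above 1 so the strict comparison is vacuous even at p == 1
        res = prognostic_screen(g, ann, detect_frac=0.0, top_n=10**9, fc_cut=0.0, p_cut=1.01)
        imputed = apply_missing_policy(g, ann, __import__("luadproteo").BIOMARKER_POLICY)
        surviving = res.loc[imputed.values.index]
        assert surviving["prefilter"].all()

    def test_rank_beyond_top_n_excludes_regardless(self, screen_cohort):
        g, ann, _ = screen_cohort
        res = prognostic_screen(g, ann, top_n=100)
        beyond = res[res["abundance_rank"] > 100]
        assert not beyond["candidate"].fillna(False).astype(bool).any()

    def test_missing_survival_stops_after_prefilter(self, screen_cohort):
        g, ann, _ = screen_cohort
        ann_nosurv = ann.copy()
        for col in ("os_time", "os_event", "dfs_time", "dfs_event"):
            ann_nosurv[col] = np.nan
        res = prognostic_screen(g, ann_nosurv)
        assert res.attrs["survival_status"] == "unavailable"
        assert res["candidate"].isna().all()
        assert res["prefilter"].notna().all()

    def test_planted_de_genes_dominate_prefilter(self, screen_cohort):
        g, ann, truth = screen_cohort
        res = prognostic_screen(g, ann, fc_cut=4.0)
        prefilter = set(res.index[res["prefilter"]])
        tumor_frac = g.values[select_samples(ann, "tumor")].notna().mean(axis=1)
        detectable = {x for x, fc in truth.de_genes.items()
                      if fc >= 2.5 and tumor_frac.get(x, 0) >= 0.7}
        # every well-detected strongly up-planted gene survives F1-F3
        assert detectable <= prefilter


class TestDiagnosticScreen:
    def test_candidates_are_secreted_and_membership_gates(self, screen_cohort):
        g, ann, truth = screen_cohort
        secretome = GeneSet("synthetic_secretome",
                            frozenset(truth.de_genes) | frozenset(truth.stage1_unique_genes))
        res = diagnostic_screen(g, ann, secretome)
        cands = res.index[res["candidate"]]
        assert len(cands) > 0
        assert all(c in secretome for c in cands)
        # dropping one candidate from the secretome removes it (D4 gate)
        dropped = cands[0]
        smaller = GeneSet("minus_one", secretome.members - {dropped})
        res2 = diagnostic_screen(g, ann, smaller)
        assert not res2.loc[dropped, "candidate"]
        assert res2.loc[dropped, ["detect_freq", "top_abundance", "de_pass"]].all()

    def test_audit_identity(self, screen_cohort):
        g, ann, truth = screen_cohort
        secretome = GeneSet("s", frozenset(truth.de_genes))
        res = diagnostic_screen(g, ann, secretome)
        flags = res[["detect_freq", "top_abundance", "de_pass", "secreted"]].astype(bool)
        assert (res["candidate"] == flags.all(axis=1)).all()

    def test_no_stage1_samples_errors(self, screen_cohort):
        g, ann, truth = screen_cohort
        ann_nostage = ann.copy()
        ann_nostage.loc[ann_nostage["stage"] == "I", "stage"] = "II"
        with pytest.raises(ValueError):
            diagnostic_screen(g, ann_nostage, GeneSet("s", frozenset(truth.de_genes)))


class TestStagePartition:
    def test_class_definitions_on_constructed_matrix(self):
        """Genes engineered per class: boosted in stage-I only, everywhere,
        entire-only (late tumors), down, and null.  Stage-I tumors are a
        strict minority so an early-only boost leaves the whole-cohort
        median (and hence the entire-cohort contrast) unmoved."""
        rng = np.random.default_rng(8)
        n_t, n_n = 24, 24
        ids = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
        ann = pd.DataFrame({"group": ["TUMOR"] * n_t + ["NAT"] * n_n}, index=ids)
        ann["stage"] = "unknown"
        ann.loc[[f"t{i}" for i in range(8)], "stage"] = "I"
        ann.loc[[f"t{i}" for i in range(8, 24)], "stage"] = "III"
        ann["subtype"] = "unknown"
        ann.loc[ann["group"] == "NAT", ["stage", "subtype"]] = "unknown"
        vals = pd.DataFrame(rng.normal(20, 0.4, (5, len(ids))),
                            index=["Gshared", "Gearly", "Gdown", "Gnull", "Glate"], columns=ids)
        tumor_cols = [f"t{i}" for i in range(n_t)]
        early_cols = [f"t{i}" for i in range(8)]
        late_cols = [f"t{i}" for i in range(8, 24)]
        vals.loc["Gshared", tumor_cols] += 3.0
        vals.loc["Gearly", early_cols] += 3.0
        vals.loc["Gdown", tumor_cols] -= 3.0
        vals.loc["Glate", late_cols] += 3.0
        part = stage_partition(GeneQuantMatrix(values=vals), ann)
        assert part.loc["Gshared", "class"] == "shared_up"
        assert part.loc["Gearly", "class"] == "stage1_unique_up"
        assert part.loc["Gdown", "class"] == "shared_down"
        assert part.loc["Gnull", "class"] == "none"
        assert part.loc["Glate", "class"] == "entire_unique_up"

    def test_planted_stage1_unique_recovery(self, screen_cohort):
        """Moderate early-only effects are mostly classed stage-I-unique;
        balanced early/late prevalence caps attainable sensitivity (the
        entire-cohort median absorbs ~half of an early-only boost)."""
        g, ann, truth = screen_cohort
        dm = apply_missing_policy(g, ann, DE_POLICY)
        part = stage_partition(dm, ann)
        tumor_frac = g.values[select_samples(ann, "tumor")].notna().mean(axis=1)
        detectable = [x for x in truth.stage1_unique_genes
                      if tumor_frac.get(x, 0) >= 0.7 and x in part.index]
        assert len(detectable) >= 3
        rate = np.mean([part.loc[x, "class"] == "stage1_unique_up" for x in detectable])
        assert rate >= 0.5


class TestGradualTrend:
    def test_definition_on_constructed_matrix(self):
        rng = np.random.default_rng(4)
        n = 15
        ids = ([f"n{i}" for i in range(n)] + [f"e{i}" for i in range(n)] + [f"l{i}" for i in range(n)])
        ann = pd.DataFrame({"group": ["NAT"] * n + ["TUMOR"] * (2 * n)}, index=ids)
        ann["stage"] = "unknown"
        ann.loc[[f"e{i}" for i in range(n)], "stage"] = "I"
        ann.loc[[f"l{i}" for i in range(n)], "stage"] = "III"
        ann["subtype"] = "unknown"
        vals = pd.DataFrame(rng.normal(20, 0.5, (3, 3 * n)),
                            index=["Gup", "Gbump", "Gdown"], columns=ids)
        vals.loc["Gup", [f"e{i}" for i in range(n)]] += 2.0
        vals.loc["Gup", [f"l{i}" for i in range(n)]] += 4.0
        vals.loc["Gbump", [f"e{i}" for i in range(n)]] += 3.0  # up then flat/down
        vals.loc["Gdown", [f"e{i}" for i in range(n)]] -= 2.0
        vals.loc["Gdown", [f"l{i}" for i in range(n)]] -= 4.0
        out = gradual_trend_screen(GeneQuantMatrix(values=vals), ann)
        assert out.loc["Gup", "class"] == "gradual_up"
        assert out.loc["Gbump", "class"] == "none"
        assert out.loc["Gdown", "class"] == "gradual_down"

    def test_planted_trends_recovered_and_null_rate_bounded(self, screen_cohort):
        g, ann, truth = screen_cohort
        dm = apply_missing_policy(g, ann, DE_POLICY)
        out = gradual_trend_screen(dm, ann, p_cut=0.05)
        tumor_frac = g.values[select_samples(ann, "tumor")].notna().mean(axis=1)
        detectable = [x for x in truth.stage_trend_genes
                      if tumor_frac.get(x, 0) >= 0.7 and x in out.index]
        assert len(detectable) >= 3
        rate = np.mean([out.loc[x, "class"] == "gradual_up" for x in detectable])
        assert rate >= 0.5
        planted = set(truth.stage_trend_genes) | set(truth.de_genes) | set(truth.stage1_unique_genes)
        nulls = out.index.difference(list(planted))
        null_rate = float((out.loc[nulls, "class"] != "none").mean())
        # independence bound on the two adjacent tests plus binomial slack
        bound = 0.05**2 + 3 * np.sqrt(0.05**2 * (1 - 0.05**2) / len(nulls))
        assert null_rate <= bound

    def test_empty_stratum_errors(self, screen_cohort):
        g, ann, _ = screen_cohort
        ann_nolate = ann.copy()
        ann_nolate.loc[ann_nolate["stage"].isin(["II", "III", "IV"]), "stage"] = "I"
        with pytest.raises(ValueError):
            gradual_trend_screen(g, ann_nolate)
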