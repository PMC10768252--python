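"""End-to-end orchestration of the analysis on real or synthetic input.

Stage order mirrors the study workflow: normalization and gene collapse,
identification-frequency sets, differential expression (tumor vs non-tumor,
SOL vs non-SOL, stage contrasts), survival screening, the biomarker
cascades, and the optional gene-dependency join.  Every threshold is
recorded in a JSON manifest next to the stage TSVs, and identical
config+seed re-runs produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dependency import annotate_dependency, median_ceres_score
from .differential import differential_table
from .frequency import classify_related_proteins, identification_fraction
from .io import (
    GeneSet,
    SCALE_LOG2,
    SCALE_QN,
    read_ceres_table,
    read_gene_set,
    read_quant_matrix,
    read_sample_annotation,
    write_gene_matrix,
    write_sample_annotation,
)
from .normalize import (
    DE_POLICY,
    apply_missing_policy,
    collapse_to_gene_level,
    log2_transform,
    quantile_normalize,
)
from .screening import diagnostic_screen, gradual_trend_screen, prognostic_screen, stage_partition
from .simulate import CohortConfig, generate_cohort

log = logging.getLogger("luadproteo")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one end-to-end run.

    Either ``matrix_path`` + ``annotation_path`` or ``synthetic`` must be
    set.  Threshold defaults are the published screening settings.
    """

    out_dir: str = "luadproteo_out"
    matrix_path: str | None = None
    matrix_dialect: str = "generic_tsv"
    matrix_scale: str = "raw"
    annotation_path: str | None = None
    secretome_path: str | None = None
    ceres_path: str | None = None
    ceres_cell_lines_path: str | None = None
    synthetic: CohortConfig | None = None
    seed: int = 0
    # thresholds (defaults = published values)
    lrp_hi: float = 0.7
    lrp_lo: float = 0.3
    de_fc_cut: float = 2.0
    de_p_cut: float = 0.05
    sol_fc_cut: float = 4.0  # abs(log2 fc) > 2
    screen_detect_frac: float = 0.7
    screen_top_n: int = 1000
    screen_fc_cut: float = 4.0
    screen_p_cut: float = 0.05
    logrank_p_cut: float = 0.05
    endpoint: str = "OS"
    ceres_threshold: float = -0.6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["de_log2fc_range"] = list(self.synthetic.de_log2fc_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = CohortConfig.from_dict(d["synthetic"])
        return cls(**d)


def _synthetic_secretome(truth, gene_universe, seed: int) -> GeneSet:
    """Synthetic stand-in for a secretome membership list: all planted DE
    genes plus a seeded 10% background draw of the gene universe."""
    import numpy as np

    rng = np.random.default_rng(seed + 101)
    background = rng.choice(gene_universe, size=max(1, len(gene_universe) // 10), replace=False)
    members = frozenset(truth.de_genes) | frozenset(background.tolist())
    return GeneSet(name="synthetic_secretome", members=members)


def run_end_to_end(config: PipelineConfig) -> Path:
    """Run every stage, writing per-stage TSVs plus ``manifest.json``.

    Returns the output directory.  Any stage failure raises with the stage
    name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
    }
    counts = manifest["stages"]
    t0 = time.time()

    def _stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        return name

    stage = _stage("load_input")
    try:
        truth = None
        secretome = None
        if config.synthetic is not None:
            sim = dataclasses.replace(config.synthetic, seed=config.seed)
            matrix, ann, truth = generate_cohort(sim)
            truth.to_json(out / "ground_truth.json")
            write_sample_annotation(ann, out / "sample_annotation.tsv")
        else:
            if not config.matrix_path or not config.annotation_path:
                raise ValueError("need matrix_path and annotation_path (or a synthetic config)")
            matrix = read_quant_matrix(
                config.matrix_path, dialect=config.matrix_dialect, scale_tag=config.matrix_scale
            )
            ann = read_sample_annotation(config.annotation_path)
        if config.secretome_path:
            secretome = read_gene_set(config.secretome_path, name=Path(config.secretome_path).stem)

        stage = _stage("normalize")
        if matrix.scale_tag == "raw":
            matrix = log2_transform(matrix)
        if matrix.scale_tag == SCALE_LOG2:
            matrix = quantile_normalize(matrix)
        assert matrix.scale_tag == SCALE_QN
        gene = collapse_to_gene_level(matrix)
        write_gene_matrix(gene, out / "gene_matrix_normalized.tsv")
        counts["normalize"] = {"n_proteins": int(matrix.values.shape[0]), "n_genes": int(gene.values.shape[0]), "n_samples": int(gene.values.shape[1])}

        stage = _stage("frequency_sets")
        freq = classify_related_proteins(identification_fraction(gene, ann), hi=config.lrp_hi, lo=config.lrp_lo)
        freq.to_csv(out / "lrp_ndrp.tsv", sep="\t", na_rep="NA")
        counts["frequency_sets"] = {
            "n_lrp": int((freq["class"] == "LRP").sum()),
            "n_ndrp": int((freq["class"] == "NDRP").sum()),
        }

        stage = _stage("differential")
        de_matrix = apply_missing_policy(gene, ann, DE_POLICY)
        de = differential_table(de_matrix, ann, ("tumor", "nontumor"), fc_cut=config.de_fc_cut, p_cut=config.de_p_cut)
        de.to_csv(out / "de_tumor_vs_nontumor.tsv", sep="\t", na_rep="NA")
        counts["differential"] = {
            "n_genes_tested": int(de["p_value"].notna().sum()),
            "n_up": int(de["up"].sum()),
            "n_down": int(de["down"].sum()),
        }
        if (ann["subtype"] == "SOL").any() and (ann.loc[ann["group"] == "TUMOR", "subtype"] != "SOL").any():
            de_sol = differential_table(de_matrix, ann, ("sol", "nonsol"), fc_cut=config.sol_fc_cut, p_cut=config.de_p_cut)
            de_sol.to_csv(out / "de_sol_vs_nonsol.tsv", sep="\t", na_rep="NA")
            counts["differential_sol"] = {"n_up": int(de_sol["up"].sum()), "n_down": int(de_sol["down"].sum())}

        stage = _stage("stage_partition")
        part = stage_partition(de_matrix, ann, fc_cut=config.de_fc_cut, p_cut=config.de_p_cut)
        part.to_csv(out / "stage_partition.tsv", sep="\t", na_rep="NA")
        counts["stage_partition"] = {c: int((part["class"] == c).sum()) for c in part["class"].unique()}

        stage = _stage("gradual_trend")
        trend = gradual_trend_screen(de_matrix, ann, p_cut=config.de_p_cut)
        trend.to_csv(out / "gradual_trend.tsv", sep="\t", na_rep="NA")
        counts["gradual_trend"] = {
            "n_gradual_up": int((trend["class"] == "gradual_up").sum()),
            "n_gradual_down": int((trend["class"] == "gradual_down").sum()),
        }

        stage = _stage("prognostic_screen")
        prog = prognostic_screen(
            gene,
            ann,
            detect_frac=config.screen_detect_frac,
            top_n=config.screen_top_n,
            fc_cut=config.screen_fc_cut,
            p_cut=config.screen_p_cut,
            logrank_p_cut=config.logrank_p_cut,
            endpoint=config.endpoint,
        )
        prog.to_csv(out / "prognostic_screen.tsv", sep="\t", na_rep="NA")
        counts["prognostic_screen"] = {
            "survival_status": prog.attrs.get("survival_status", "unknown"),
            "n_detect": int(prog["detect_freq"].sum()),
            "n_prefilter": int(prog["prefilter"].sum()),
            "n_candidates": int(prog["candidate"].fillna(False).astype(bool).sum()),
        }

        stage = _stage("diagnostic_screen")
        if secretome is None and truth is not None:
            secretome = _synthetic_secretome(truth, list(gene.gene_names), config.seed)
        if secretome is not None and (ann["stage"] == "I").any():
            diag = diagnostic_screen(
                gene,
                ann,
                secretome,
                detect_frac=config.screen_detect_frac,
                top_n=config.screen_top_n,
                fc_cut=config.screen_fc_cut,
                q_cut=config.screen_p_cut,
            )
            diag.to_csv(out / "diagnostic_screen.tsv", sep="\t", na_rep="NA")
            counts["diagnostic_screen"] = {"n_candidates": int(diag["candidate"].sum())}
        else:
            counts["diagnostic_screen"] = {"skipped": "no secretome list or no stage-I samples"}

        stage = _stage("dependency_annotation")
        if config.ceres_path:
            ceres = read_ceres_table(config.ceres_path)
            panel = None
            if config.ceres_cell_lines_path:
                panel = read_gene_set(config.ceres_cell_lines_path, "cell_lines").members
            dep = median_ceres_score(ceres, panel, threshold=config.ceres_threshold)
            annotated = annotate_dependency(prog, dep)
            annotated.to_csv(out / "prognostic_screen_with_dependency.tsv", sep="\t", na_rep="NA")
            counts["dependency_annotation"] = {
                "n_dependent_candidates": int(
                    (annotated["candidate"].fillna(False).astype(bool) & annotated["dependent_flag"].fillna(False)).sum()
                )
            }
        else:
            counts["dependency_annotation"] = {"skipped": "no CERES table supplied"}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
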