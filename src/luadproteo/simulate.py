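"""Synthetic LUAD proteome cohorts with a ground-truth manifest.

The generator emulates a label-free tissue-proteome study: paired
tumor/adjacent-tissue samples plus a small benign-disease group, log2
intensity values with abundance-dependent (MNAR) missingness, planted
tumor-vs-non-tumor fold changes, stage-linked effects, and survival times
whose hazard depends on planted prognostic genes.

Default sizes and detection parameters reproduce the structure of a
220-sample cohort (103 tumor/NAT pairs + 14 benign) quantifying ~11.7k
proteins that collapse to ~11.2k gene symbols, with more proteins
identified per tumor than per non-tumor sample.  The detection threshold
and per-group offsets were chosen in closed form (Gaussian abundance x
logistic detection) so the expected per-sample identified-gene counts sit
near 7,400 (tumor), 5,900 (NAT) and 5,700 (benign).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GeneQuantMatrix, ProteinQuantMatrix, SCALE_LOG2, select_samples

STAGE_ORDINAL = {"I": 1, "II": 2, "III": 2, "IV": 2}  # non-tumor stratum = 0


def _default_stage_probs() -> dict:
    # 51 of 103 tumors early-stage; the II/III/IV split is a plausible spread
    return {"I": 0.495, "II": 0.25, "III": 0.165, "IV": 0.09}


def _default_subtype_probs() -> dict:
    # proportions of the 103-tumor cohort: ACI 49, PAP 18, SOL 22, LEP 5, MIX 8
    return {"ACI": 0.48, "PAP": 0.18, "SOL": 0.21, "LEP": 0.05, "MIX": 0.08}


def _default_detect_offsets() -> dict:
    return {"TUMOR": -1.0, "NAT": 0.0, "BENIGN": 0.15}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Abundances are log2 intensities.  Detection is missing-not-at-random:
    cell (g, s) is observed with probability
    sigmoid(detect_slope * (x_gs - (detect_threshold + offset_group(s)))),
    so low-abundance proteins drop out and groups with a lower offset
    identify more proteins.
    """

    n_patients_paired: int = 103
    n_benign: int = 14
    n_proteins: int = 11726
    n_extra_isoforms: int = 492  # proteins beyond one per gene; genes = proteins - this
    stage_probs: dict = field(default_factory=_default_stage_probs)
    subtype_probs: dict = field(default_factory=_default_subtype_probs)
    baseline_mean: float = 25.0
    baseline_sd: float = 2.5
    noise_sd: float = 1.2
    detect_threshold: float = 24.8
    group_detect_offsets: dict = field(default_factory=_default_detect_offsets)
    detect_slope: float = 1.0
    n_planted_de: int = 30
    de_log2fc_range: tuple = (2.0, 4.0)
    de_frac_down: float = 0.3
    n_planted_prognostic: int = 5
    prognostic_log_hazard: float = 0.8
    # prognostic biomarkers in this screen are by construction tumor-elevated
    # (they must pass the fold-change gate), so planted prognostic genes also
    # carry a tumor boost
    prognostic_log2fc: float = 3.0
    n_planted_stage_trend: int = 20
    stage_trend_step: float = 1.0  # log2 increment per stage stratum (one doubling)
    n_planted_stage1_unique: int = 20
    # moderate by design: with stage-I tumors ~half the cohort, a large
    # early-only shift would drag the whole-cohort median past a 2-fold cut,
    # making the planted effect "shared" rather than early-stage-specific
    stage1_unique_log2fc: float = 1.5
    baseline_hazard: float = 0.0173  # events/month; median OS ~ 40 months
    censor_rate: float = 0.35
    follow_up_months: float = 120.0
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_proteins - self.n_extra_isoforms

    def validate(self) -> None:
        if self.n_patients_paired < 1:
            raise ValueError("need at least one tumor/NAT pair")
        if self.n_benign < 0 or self.n_proteins < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_extra_isoforms < self.n_proteins:
            raise ValueError("n_extra_isoforms must be in [0, n_proteins)")
        for name, probs in (("stage_probs", self.stage_probs), ("subtype_probs", self.subtype_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")
        n_planted = (
            self.n_planted_de
            + self.n_planted_prognostic
            + self.n_planted_stage_trend
            + self.n_planted_stage1_unique
        )
        if n_planted > self.n_genes:
            raise ValueError("planted gene counts exceed the gene universe")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "de_log2fc_range" in d:
            d["de_log2fc_range"] = tuple(d["de_log2fc_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Manifest of planted effects, for recovery scoring."""

    de_genes: dict  # symbol -> true tumor-vs-non-tumor log2 fold change
    prognostic_genes: dict  # symbol -> hazard coefficient per log2 unit
    stage_trend_genes: dict  # symbol -> per-stratum log2 increment
    stage1_unique_genes: dict  # symbol -> log2 fold change in stage-I tumors only
    detection_params: dict  # threshold/offsets/slope actually used

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _apportion(probs: Mapping[str, float], n: int) -> np.ndarray:
    """Integer label counts by largest remainder; returns the label vector."""
    labels = sorted(probs)
    quota = np.array([probs[k] * n for k in labels])
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return np.repeat(labels, counts)


def generate_cohort(config: CohortConfig) -> tuple[ProteinQuantMatrix, pd.DataFrame, GroundTruth]:
    """Simulate one cohort; same config (incl. seed) gives bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs, n_benign = config.n_patients_paired, config.n_benign
    n_genes, n_prot = config.n_genes, config.n_proteins

    gene_universe = np.array([f"G{i:05d}" for i in range(n_genes)])
    protein_ids = np.array([f"P{i:05d}" for i in range(n_prot)])
    # one protein per gene plus extra isoforms for randomly chosen genes
    iso_genes = rng.choice(n_genes, size=config.n_extra_isoforms, replace=False)
    gene_of_protein = np.concatenate([np.arange(n_genes), iso_genes])

    # --- samples ------------------------------------------------------------
    tumor_ids = [f"T{i + 1:03d}" for i in range(n_pairs)]
    nat_ids = [f"N{i + 1:03d}" for i in range(n_pairs)]
    benign_ids = [f"B{i + 1:03d}" for i in range(n_benign)]
    sample_ids = tumor_ids + nat_ids + benign_ids
    groups = ["TUMOR"] * n_pairs + ["NAT"] * n_pairs + ["BENIGN"] * n_benign
    patient = [f"PT{i + 1:03d}" for i in range(n_pairs)] * 2 + [None] * n_benign

    # stage/subtype composition is fixed (largest-remainder apportionment of
    # the probabilities), then randomly assigned to patients: study cohorts
    # have a fixed composition, not an iid-sampled one
    stage_lab = rng.permutation(_apportion(config.stage_probs, n_pairs))
    subtype_lab = rng.permutation(_apportion(config.subtype_probs, n_pairs))

    # --- planted effects ------------------------------------------------------
    planted = rng.choice(
        n_genes,
        size=config.n_planted_de
        + config.n_planted_prognostic
        + config.n_planted_stage_trend
        + config.n_planted_stage1_unique,
        replace=False,
    )
    i = 0
    de_idx = planted[i : i + config.n_planted_de]; i += config.n_planted_de
    prog_idx = planted[i : i + config.n_planted_prognostic]; i += config.n_planted_prognostic
    trend_idx = planted[i : i + config.n_planted_stage_trend]; i += config.n_planted_stage_trend
    s1_idx = planted[i : i + config.n_planted_stage1_unique]

    lo, hi = config.de_log2fc_range
    de_fc = rng.uniform(lo, hi, size=len(de_idx))
    n_down = int(round(config.de_frac_down * len(de_idx)))
    if n_down:
        de_fc[rng.choice(len(de_idx), size=n_down, replace=False)] *= -1

    # --- gene-level effect matrix Delta[gene, sample] -------------------------
    n_samples = len(sample_ids)
    delta = np.zeros((n_genes, n_samples))
    tumor_cols = np.arange(n_pairs)
    delta[np.ix_(de_idx, tumor_cols)] += de_fc[:, None]
    if len(prog_idx):
        delta[np.ix_(prog_idx, tumor_cols)] += config.prognostic_log2fc
    stage_ord = np.zeros(n_samples)
    stage_ord[tumor_cols] = [STAGE_ORDINAL[s] for s in stage_lab]
    delta[trend_idx, :] += config.stage_trend_step * stage_ord[None, :]
    s1_cols = tumor_cols[stage_lab == "I"]
    if len(s1_cols):
        delta[np.ix_(s1_idx, s1_cols)] += config.stage1_unique_log2fc

    # --- abundances and MNAR detection ----------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_prot)
    noise = rng.normal(0.0, config.noise_sd, size=(n_prot, n_samples))
    x = baseline[:, None] + delta[gene_of_protein, :] + noise

    offsets = np.array([config.group_detect_offsets[g] for g in groups])
    p_detect = _sigmoid(config.detect_slope * (x - (config.detect_threshold + offsets[None, :])))
    observed = rng.random((n_prot, n_samples)) < p_detect
    values = np.where(observed, x, np.nan)

    # --- survival (tumor samples only) -----------------------------------------
    # hazard uses each prognostic gene's patient-specific deviation from its
    # structural expectation (baseline + planted group effect): neither the
    # random per-gene baseline nor the tumor-wide boost shifts the cohort
    # hazard scale, only between-patient biomarker variation does
    log_h = np.full(n_pairs, np.log(config.baseline_hazard))
    for gi in prog_idx:
        prots = np.flatnonzero(gene_of_protein == gi)
        gene_eps = (x[prots, :n_pairs] - baseline[prots][:, None]).mean(axis=0) - delta[gi, :n_pairs]
        log_h += config.prognostic_log_hazard * gene_eps
    hazard = np.exp(np.clip(log_h, -30, 5))
    t_death = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        c_rate = config.baseline_hazard * config.censor_rate / (1 - config.censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n_pairs)
    else:
        t_cens = np.full(n_pairs, np.inf)
    t_cens = np.minimum(t_cens, config.follow_up_months)
    os_time = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(int)
    t_recur = rng.exponential(1.0 / (0.4 * hazard))
    dfs_raw = np.minimum(t_recur, t_death)
    dfs_time = np.minimum(dfs_raw, t_cens)
    dfs_event = (dfs_raw <= t_cens).astype(int)
    tiny = 1e-3  # survival times must be positive
    os_time = np.maximum(os_time, tiny)
    dfs_time = np.maximum(dfs_time, tiny)

    # --- assemble ---------------------------------------------------------------
    ann = pd.DataFrame(
        {
            "group": groups,
            "patient_id": pd.array(patient, dtype="string"),
            "stage": ["unknown"] * n_samples,
            "subtype": ["unknown"] * n_samples,
            "os_time": np.nan,
            "os_event": np.nan,
            "dfs_time": np.nan,
            "dfs_event": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ann.iloc[:n_pairs, ann.columns.get_loc("stage")] = stage_lab
    ann.iloc[:n_pairs, ann.columns.get_loc("subtype")] = subtype_lab
    ann.iloc[:n_pairs, ann.columns.get_loc("os_time")] = np.round(os_time, 3)
    ann.iloc[:n_pairs, ann.columns.get_loc("os_event")] = os_event
    ann.iloc[:n_pairs, ann.columns.get_loc("dfs_time")] = np.round(dfs_time, 3)
    ann.iloc[:n_pairs, ann.columns.get_loc("dfs_event")] = dfs_event

    matrix = ProteinQuantMatrix(
        values=pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"), columns=sample_ids),
        gene_names=pd.Series(gene_universe[gene_of_protein], index=protein_ids, dtype="string"),
        scale_tag=SCALE_LOG2,
    )
    truth = GroundTruth(
        de_genes={gene_universe[g]: float(fc) for g, fc in zip(de_idx, de_fc)},
        prognostic_genes={gene_universe[g]: config.prognostic_log_hazard for g in prog_idx},
        stage_trend_genes={gene_universe[g]: config.stage_trend_step for g in trend_idx},
        stage1_unique_genes={gene_universe[g]: config.stage1_unique_log2fc for g in s1_idx},
        detection_params={
            "threshold": config.detect_threshold,
            "slope": config.detect_slope,
            "offsets": dict(config.group_detect_offsets),
        },
    )
    return matrix, ann, truth


@dataclass
class RecoveryReport:
    sensitivity: float
    specificity: float
    n_planted: int
    n_detectable: int
    n_candidates: int
    true_positives: int

    def as_dict(self) -> dict:
        return asdict(self)


def truth_recovery_report(
    candidates,
    truth_genes: Mapping[str, float],
    matrix: GeneQuantMatrix | ProteinQuantMatrix,
    ann: pd.DataFrame,
    max_undetected_frac: float = 0.3,
) -> RecoveryReport:
    """Score a screen's candidate list against one planted-gene map.

    A planted gene missing in more than ``max_undetected_frac`` of tumor
    samples is excluded from the sensitivity denominator: the screens are
    explicitly restricted to well-detected proteins, so an effect the
    instrument cannot see is not a recoverable effect.
    """
    if isinstance(candidates, pd.DataFrame):
        if "candidate" not in candidates.columns:
            raise ValueError("screen frame lacks a 'candidate' column")
        cand = set(candidates.index[candidates["candidate"].fillna(False).astype(bool)])
    else:
        cand = set(candidates)
    if isinstance(matrix, ProteinQuantMatrix):
        universe = set(matrix.gene_names.dropna())
        tumor_obs_frac = (
            matrix.values[select_samples(ann, "tumor")].notna().groupby(matrix.gene_names).max().mean(axis=1)
        )
    else:
        universe = set(matrix.gene_names)
        tumor_obs_frac = matrix.values[select_samples(ann, "tumor")].notna().mean(axis=1)
    planted = set(truth_genes)
    if not planted & universe:
        raise ValueError("planted genes and matrix gene universe are disjoint")
    detectable = {g for g in planted if g in universe and tumor_obs_frac.get(g, 0.0) >= 1 - max_undetected_frac}
    tp = len(cand & detectable)
    negatives = universe - planted
    fp = len(cand & negatives)
    sensitivity = tp / len(detectable) if detectable else float("nan")
    specificity = (len(negatives) - fp) / len(negatives) if negatives else float("nan")
    return RecoveryReport(
        sensitivity=sensitivity,
        specificity=specificity,
        n_planted=len(planted),
        n_detectable=len(detectable),
        n_candidates=len(cand),
        true_positives=tp,
    )
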