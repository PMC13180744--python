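"""End-to-end orchestration of the biomarker-discovery analysis.

Stage order mirrors the study workflow: per-cohort differential
expression -> bootstrap stability -> cross-cohort consensus -> methylome
calls -> transcriptome/methylome integration -> external validation ->
ML evaluation -> cell-type enrichment.  ``run_simulated`` drives the whole
pipeline on synthetic data and scores every stage against the planted
truth manifest; every threshold used is serialized into the run manifest,
which (with the seed) suffices to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .celltype import deg_enrichment_score, expressed_gene_sets, qc_filter
from .consensus import DirectionalGeneSet, frequency_consensus
from .dge import ExpressionMatrix, bootstrap_stability, call_degs, de_test, normalize_log_expression
from .integrate import integrate_signature
from .marker_validation import auc_table, direction_concordance, group_log_ratio, zscore_matrix
from .methylome import classify_dmgs
from .ml_models import CVConfig, loocv_evaluate, nested_cv_evaluate, permutation_test, rfe_select
from .simulate import SimulationConfig, make_truth, simulate_bulk_cohort, simulate_cell_matrix, simulate_methylome, simulate_validation_set

__all__ = ["PipelineConfig", "run_simulated"]

log = logging.getLogger("fibromark")


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, defaulting to the study's values."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # DE calling
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    engine: str = "welch"
    # bootstrap stability
    bootstrap_B: int = 500
    stability_threshold: float = 0.6
    stability_comparator: str = "gt"
    apply_stability_filter: bool = True
    # consensus
    min_freq: int = 2
    # methylome
    meth_effect: float = 0.1
    meth_alpha: float = 0.05
    meth_criterion: str = "raw_p"
    # cell QC
    qc_min_features: int = 200
    qc_max_mito: float = 0.10
    n_cell_patients: int = 4
    # ML
    ml: CVConfig = field(default_factory=lambda: CVConfig(model="svm"))
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if isinstance(self.ml, dict):
            self.ml = CVConfig(**self.ml)
        if self.bootstrap_B <= 0:
            raise ValueError("bootstrap_B must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.meth_alpha < 1):
            raise ValueError("alpha values must be in (0,1)")
        if self.meth_effect <= 0:
            raise ValueError("meth_effect must be positive")
        if self.min_freq < 1:
            raise ValueError("min_freq must be >= 1")
        # the simulation and ML substreams key off the global seed
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.ml = dataclasses.replace(self.ml, seed=self.seed)

    @classmethod
    def scaled_default(cls, seed: int = 0) -> "PipelineConfig":
        """Desk-scale sizing for the simulated end-to-end run: B=100
        bootstrap iterations and 200 permutations with the linear-SVM
        family, everything else at the study defaults."""
        return cls(
            bootstrap_B=100,
            ml=CVConfig(model="svm", n_permutations=200),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        import json

        # json round-trip turns nested tuples into lists (YAML/JSON safe)
        return json.loads(json.dumps(dataclasses.asdict(self)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # preserve the offending stage name
                raise RuntimeError(f"stage '{name}' failed: {e}") from e

        return wrapper

    return deco


def _recall(called: set[str], planted: set[str]) -> float:
    return len(called & planted) / len(planted) if planted else float("nan")


def _precision(called: set[str], planted: set[str]) -> float:
    return len(called & planted) / len(called) if called else float("nan")


def run_simulated(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline on synthetic inputs and score recovery.

    Writes every stage's inputs/outputs plus a run manifest (thresholds,
    output hashes, recovery report) under ``outdir`` and returns the
    manifest as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    truth = make_truth(sim)

    # ---- stage: synthesize inputs -------------------------------------
    @_stage("synthetic_data")
    def _synthesize():
        cohorts = {}
        for c in sim.cohorts:
            em, _ = simulate_bulk_cohort(sim, c, truth)
            fio.write_expression(
                em, outdir / f"{c.name}_counts.tsv", outdir / f"{c.name}_samples.tsv"
            )
            cohorts[c.name] = em
        meth = simulate_methylome(sim, truth)
        fio.write_methylation(meth, outdir / "methylation.csv")
        val = simulate_validation_set(sim, truth)
        fio.write_expression(
            val, outdir / "validation_matrix.tsv", outdir / "validation_samples.tsv"
        )
        cells = []
        for p in range(config.n_cell_patients):
            cm = simulate_cell_matrix(sim, truth, patient=p)
            fio.write_10x_triplet(cm, outdir / f"patient_{p}")
            cells.append(cm)
        fio.write_json(truth.to_dict(), outdir / "truth.json")
        return cohorts, meth, val, cells

    cohorts, meth, val, cells = _synthesize()

    # ---- stage: per-cohort DE + bootstrap stability -------------------
    @_stage("dge")
    def _dge():
        per_cohort = []
        stability = {}
        for c in sim.cohorts:
            em = cohorts[c.name]
            res = de_test(em, engine=config.engine)
            res.table.to_csv(outdir / f"{c.name}_de.tsv", sep="\t", index_label="gene")
            up, down = call_degs(
                res, lfc=config.lfc_threshold, alpha=config.alpha, criterion=c.criterion
            )
            prof = bootstrap_stability(
                em,
                B=config.bootstrap_B,
                threshold=config.stability_threshold,
                comparator=config.stability_comparator,
                criterion=c.criterion,
                lfc=config.lfc_threshold,
                alpha=config.alpha,
                engine=config.engine,
                seed=config.seed,
            )
            prof.table.to_csv(
                outdir / f"{c.name}_stability.tsv", sep="\t", index_label="gene"
            )
            stability[c.name] = prof
            if config.apply_stability_filter:
                up &= prof.retained_genes
                down &= prof.retained_genes
            per_cohort.append(DirectionalGeneSet(cohort=c.name, up=up, down=down))
        return per_cohort, stability

    per_cohort, stability = _dge()

    # ---- stage: consensus ---------------------------------------------
    @_stage("consensus")
    def _consensus():
        cons = frequency_consensus(per_cohort, min_freq=config.min_freq)
        fio.write_json(cons.to_dict(), outdir / "consensus.json")
        return cons

    cons = _consensus()

    # ---- stage: methylome ----------------------------------------------
    @_stage("methylome")
    def _methylome():
        dmg = classify_dmgs(
            meth,
            effect=config.meth_effect,
            alpha=config.meth_alpha,
            criterion=config.meth_criterion,
        )
        fio.write_gene_list(dmg.hyper, outdir / "hyper.txt")
        fio.write_gene_list(dmg.hypo, outdir / "hypo.txt")
        fio.write_gene_list(dmg.ambiguous, outdir / "ambiguous.txt")
        return dmg

    dmg = _methylome()

    # ---- stage: integration --------------------------------------------
    @_stage("integrate")
    def _integrate():
        sig = integrate_signature(cons.up, cons.down, dmg)
        sig.table.to_csv(outdir / "signature.tsv", sep="\t", index_label="gene")
        fio.write_json(sig.to_dict(), outdir / "signature.json")
        return sig

    sig = _integrate()

    # ---- stage: external validation ------------------------------------
    @_stage("marker_validation")
    def _validate():
        consensus_genes = sorted(cons.up | cons.down)
        aucs = auc_table(val, genes=consensus_genes)
        aucs.to_csv(outdir / "validation_auc.tsv", sep="\t", index_label="gene")
        discovery = {g: "up" for g in cons.up} | {g: "down" for g in cons.down}
        report = direction_concordance(discovery, aucs)
        ratios = group_log_ratio(val)
        ratios.loc[consensus_genes].to_csv(
            outdir / "validation_log_ratio.tsv", sep="\t", index_label="gene", header=True
        )
        zmat, flat = zscore_matrix(val)
        zmat.loc[[g for g in consensus_genes if g in zmat.index]].to_csv(
            outdir / "validation_zscore.tsv", sep="\t", index_label="gene"
        )
        fio.write_json(
            {
                "n_concordant_up": report.n_concordant_up,
                "total_up": report.total_up,
                "n_concordant_down": report.n_concordant_down,
                "total_down": report.total_down,
                "missing": report.missing,
                "zero_variance_genes": flat,
            },
            outdir / "concordance.json",
        )
        return aucs, report

    aucs, concord = _validate()

    # ---- stage: ML ------------------------------------------------------
    @_stage("ml_models")
    def _ml():
        consensus_genes = sorted(cons.up | cons.down)
        mats, labels = [], []
        for c in sim.cohorts:
            logm = normalize_log_expression(cohorts[c.name])
            mats.append(logm.values.loc[consensus_genes].T)
            labels.append(logm.groups)
        X = pd.concat(mats, axis=0)
        y = pd.concat(labels).loc[X.index].to_numpy()
        loocv_all = loocv_evaluate(X, y, config.ml)
        top = rfe_select(X, y, config.ml)
        loocv_top = loocv_evaluate(X[top], y, config.ml)
        nested = nested_cv_evaluate(X[top], y, config.ml)
        p_perm, perm_stats = permutation_test(X[top], y, config.ml, nested.mean_auroc)
        loocv_all.predictions.to_csv(outdir / "loocv_predictions.tsv", sep="\t")
        fio.write_json(
            {
                "loocv_all_features": {"auroc": loocv_all.auroc, "auprc": loocv_all.auprc,
                                       **loocv_all.notes},
                "selected_features": top,
                "loocv_top_features": {"auroc": loocv_top.auroc, "auprc": loocv_top.auprc},
                "nested_cv": {"mean_auroc": nested.mean_auroc, "sd_auroc": nested.sd_auroc,
                              "fold_scores": nested.fold_scores},
                "permutation": {"p_value": p_perm,
                                "n_permutations": config.ml.n_permutations,
                                "null_mean": float(np.mean(perm_stats))},
            },
            outdir / "ml_report.json",
        )
        return loocv_all, loocv_top, top, nested, p_perm, perm_stats

    loocv_all, loocv_top, top_features, nested, p_perm, perm_stats = _ml()

    # ---- stage: cell-type enrichment ------------------------------------
    @_stage("celltype_enrichment")
    def _celltype():
        deg_set = set(cons.up)
        per_patient = {}
        for p, cm in enumerate(cells):
            filtered, qc_log = qc_filter(
                cm, min_features=config.qc_min_features, max_mito=config.qc_max_mito
            )
            expressed, zero_var = expressed_gene_sets(filtered)
            universe = set(filtered.genes) - zero_var
            scores = deg_enrichment_score(expressed, deg_set, universe)
            scores.to_csv(outdir / f"patient_{p}_celltype_scores.csv")
            fio.write_json(qc_log, outdir / f"patient_{p}_qc.json")
            per_patient[p] = scores
        return per_patient

    celltype_scores = _celltype()

    # ---- recovery report -------------------------------------------------
    planted_stability = {
        c.name: float(
            stability[c.name]
            .table.loc[sorted(truth.up_genes | truth.down_genes), "stability_score"]
            .mean()
        )
        for c in sim.cohorts
    }
    null_genes = [
        g for g in sim.gene_ids() if g not in truth.up_genes | truth.down_genes
    ]
    null_retention = {
        c.name: float(stability[c.name].table.loc[null_genes, "retained"].mean())
        for c in sim.cohorts
    }
    sig_set = set(sig.genes)
    program_rank = {}
    for p, scores in celltype_scores.items():
        order = scores["normalized_score"].sort_values(ascending=False)
        program_rank[p] = int(list(order.index).index(sim.program_celltype)) + 1

    recovery = {
        "consensus_up_recall": _recall(cons.up, truth.up_genes),
        "consensus_up_precision": _precision(cons.up, truth.up_genes),
        "consensus_down_recall": _recall(cons.down, truth.down_genes),
        "consensus_down_precision": _precision(cons.down, truth.down_genes),
        "dmg_hyper_recall": _recall(dmg.hyper, truth.hyper_genes),
        "dmg_hypo_recall": _recall(dmg.hypo, truth.hypo_genes),
        "signature_recall": _recall(sig_set, truth.signature_genes),
        "signature_precision": _precision(sig_set, truth.signature_genes),
        "signature_exact_match": sig_set == truth.signature_genes,
        "planted_mean_stability": planted_stability,
        "null_retention_rate": null_retention,
        "validation_concordance": concord.fraction_concordant,
        "loocv_auroc_all": loocv_all.auroc,
        "loocv_auroc_top": loocv_top.auroc,
        "nested_auroc_mean": nested.mean_auroc,
        "permutation_p": p_perm,
        "program_celltype_rank": program_rank,
    }

    manifest = {
        "config": config.to_dict(),
        "recovery": recovery,
        "selected_features": top_features,
        "outputs": {
            str(f.relative_to(outdir)): _sha256(f)
            for f in sorted(outdir.glob("**/*"))
            if f.is_file() and f.name != "manifest.json"
        },
    }
    fio.write_json(manifest, outdir / "manifest.json")
    return manifest
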