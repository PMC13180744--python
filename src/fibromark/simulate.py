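"""Synthetic multi-omics data with planted ground truth.

Every pipeline input is generated here with a known truth manifest so
each downstream stage can be scored against what was planted, without any
external download:

* bulk RNA-seq cohorts: negative-binomial counts (mean/dispersion
  parameterization) with log-normal library sizes, planted |log2FC| = 2
  on the up/down gene sets;
* a probe-level methylome: beta-distributed replicate betas (7 case vs 5
  control replicates) with planted |delta-beta| = 0.2 shifts on hyper/hypo
  gene sets that overlap the planted DEGs so the integrated signature
  ((up ∩ hypo) ∪ (down ∩ hyper)) is known in advance;
* a continuous validation cohort preserving planted directions, with
  dysplasia/non-dysplasia case subgroups;
* a 10x-style genes x spots count matrix with labelled cell types, a
  planted cell-type expression program, mito-prefixed genes and an
  explicit list of planted QC violators.

One global seed expands into named substreams, so adding a generator
never shifts the draws of an existing one.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from ._rng import component_rng
from .celltype import CellMatrix
from .dge import ExpressionMatrix
from .methylome import MethylationTable, compute_delta_beta

__all__ = [
    "CohortDesign",
    "SimulationConfig",
    "SimulationTruth",
    "make_truth",
    "simulate_bulk_cohort",
    "simulate_methylome",
    "simulate_validation_set",
    "simulate_cell_matrix",
]


@dataclass(frozen=True)
class CohortDesign:
    """One bulk cohort: sample sizes and the significance criterion it uses."""

    name: str
    n_case: int
    n_control: int
    criterion: str = "fdr"  # "fdr" | "raw_p"


def _default_cohorts() -> tuple[CohortDesign, ...]:
    # Recovery-grade sizes; the small-cohort criteria pattern (FDR for the
    # larger cohort, raw p for the two small ones) is preserved.
    return (
        CohortDesign("cohort1", 20, 20, "fdr"),
        CohortDesign("cohort2", 20, 20, "raw_p"),
        CohortDesign("cohort3", 20, 20, "raw_p"),
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with planted effects clearing the
    pipeline's calling thresholds by construction (|log2FC| >= 1,
    |delta-beta| >= 0.1)."""

    n_genes: int = 2000
    cohorts: tuple[CohortDesign, ...] = field(default_factory=_default_cohorts)
    base_mean: float = 100.0
    base_sigma: float = 1.0  # log-normal spread of per-gene base means
    dispersion: float = 0.1
    lfc: float = 2.0  # planted |log2 fold change|
    library_sigma: float = 0.25  # log-normal spread of library size factors
    # planted truth-set sizes
    n_up: int = 40
    n_down: int = 40
    n_hyper: int = 60
    n_hypo: int = 60
    n_up_hypo: int = 4  # up ∩ hypo arm of the signature
    n_down_hyper: int = 7  # down ∩ hyper arm
    # methylome
    delta_beta: float = 0.2
    beta_concentration: float = 150.0
    meth_case_n: int = 7
    meth_control_n: int = 5
    multi_gene_probes: int = 20
    # validation cohort
    n_val_case: int = 4  # split evenly dysplasia / no_dysplasia
    n_val_control: int = 2
    val_noise_sd: float = 0.5
    # cell matrix
    celltypes: tuple[str, ...] = (
        "Keratinocyte",
        "Fibroblast",
        "EpithelialCell",
        "DendriticCell",
    )
    program_celltype: str = "Keratinocyte"
    spots_per_type: int = 60
    program_size: int = 40  # program genes for non-designated cell types
    program_fold: float = 8.0
    cell_base_mean: float = 0.3
    n_mito: int = 13
    mito_prefix: str = "MT-"
    mito_target_fraction: float = 0.04
    qc_violation_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohorts = tuple(
            c if isinstance(c, CohortDesign) else CohortDesign(**c) for c in self.cohorts
        )
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for c in self.cohorts:
            if c.n_case < 2 or c.n_control < 2:
                raise ValueError(f"cohort {c.name}: each group needs >= 2 samples")
            if c.criterion not in ("fdr", "raw_p"):
                raise ValueError(f"cohort {c.name}: bad criterion {c.criterion!r}")
        if self.base_mean <= 0 or self.dispersion < 0:
            raise ValueError("base_mean must be > 0 and dispersion >= 0")
        if self.lfc != 0 and self.lfc < 1.0:
            raise ValueError("planted |log2FC| must be 0 or >= 1")
        if self.delta_beta != 0 and self.delta_beta < 0.1:
            raise ValueError("planted |delta-beta| must be 0 or >= 0.1")
        if self.delta_beta >= 0.45:
            raise ValueError(
                "delta_beta >= 0.45 pushes group beta means outside [0,1]"
            )
        if self.n_up_hypo > min(self.n_up, self.n_hypo):
            raise ValueError("n_up_hypo exceeds planted up/hypo set sizes")
        if self.n_down_hyper > min(self.n_down, self.n_hyper):
            raise ValueError("n_down_hyper exceeds planted down/hyper set sizes")
        needed = self.n_up + self.n_down + self.n_hyper + self.n_hypo
        if needed > self.n_genes:
            raise ValueError("planted sets do not fit in the gene universe")
        if self.program_celltype not in self.celltypes:
            raise ValueError(
                f"program cell type {self.program_celltype!r} not among {self.celltypes}"
            )
        if not (0 <= self.qc_violation_frac < 1):
            raise ValueError("qc_violation_frac must be in [0, 1)")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be positive")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class SimulationTruth:
    """The planted truth manifest all recovery checks score against."""

    up_genes: set[str]
    down_genes: set[str]
    hyper_genes: set[str]
    hypo_genes: set[str]
    celltype_program: dict[str, set[str]]
    lfc: float
    delta_beta: float
    qc_violators: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("up and down planted sets must be disjoint")

    @property
    def signature_genes(self) -> set[str]:
        return (self.up_genes & self.hypo_genes) | (self.down_genes & self.hyper_genes)

    def to_dict(self) -> dict:
        return {
            "up_genes": sorted(self.up_genes),
            "down_genes": sorted(self.down_genes),
            "hyper_genes": sorted(self.hyper_genes),
            "hypo_genes": sorted(self.hypo_genes),
            "signature_genes": sorted(self.signature_genes),
            "celltype_program": {k: sorted(v) for k, v in self.celltype_program.items()},
            "lfc": self.lfc,
            "delta_beta": self.delta_beta,
            "qc_violators": {str(k): v for k, v in self.qc_violators.items()},
        }


def make_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw the planted gene sets (deterministic from the config seed).

    The hypo set contains exactly n_up_hypo of the up genes plus unrelated
    genes; the hyper set contains exactly n_down_hyper of the down genes
    plus unrelated genes.  Expression and methylation arms outside those
    intersections never overlap, so the planted signature is exactly the
    two intersections.
    """
    rng = component_rng(config.seed, "truth")
    genes = np.array(config.gene_ids())
    perm = rng.permutation(len(genes))

    def take(n: int, cursor: int) -> tuple[set[str], int]:
        return set(genes[perm[cursor : cursor + n]]), cursor + n

    cur = 0
    up, cur = take(config.n_up, cur)
    down, cur = take(config.n_down, cur)
    hypo_extra, cur = take(config.n_hypo - config.n_up_hypo, cur)
    hyper_extra, cur = take(config.n_hyper - config.n_down_hyper, cur)

    up_sorted = sorted(up)
    down_sorted = sorted(down)
    hypo = set(
        list(rng.choice(up_sorted, size=config.n_up_hypo, replace=False))
        if config.n_up_hypo
        else []
    ) | hypo_extra
    hyper = set(
        list(rng.choice(down_sorted, size=config.n_down_hyper, replace=False))
        if config.n_down_hyper
        else []
    ) | hyper_extra

    program: dict[str, set[str]] = {}
    used = up | down | hyper | hypo
    free = [g for g in genes[perm[cur:]] if g not in used]
    fcur = 0
    for ct in config.celltypes:
        if ct == config.program_celltype:
            # the designated type's program is the planted DEG set itself
            program[ct] = set(up_sorted)
        else:
            program[ct] = set(free[fcur : fcur + config.program_size])
            fcur += config.program_size
    if fcur > len(free):
        raise ValueError("not enough free genes for cell-type programs")

    return SimulationTruth(
        up_genes=up,
        down_genes=down,
        hyper_genes=hyper,
        hypo_genes=hypo,
        celltype_program=program,
        lfc=config.lfc,
        delta_beta=config.delta_beta,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) counts; dispersion 0 degrades to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_bulk_cohort(
    config: SimulationConfig,
    cohort: CohortDesign | int = 0,
    truth: SimulationTruth | None = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Negative-binomial count cohort with planted fold changes.

    Gene base means are log-normal around ``base_mean``; case means of
    planted up (down) genes are the control mean times 2^lfc (2^-lfc);
    library size factors are log-normal so normalization matters.
    """
    if truth is None:
        truth = make_truth(config)
    if isinstance(cohort, int):
        cohort = config.cohorts[cohort]
    rng = component_rng(config.seed, f"bulk-{cohort.name}")

    genes = config.gene_ids()
    base = rng.lognormal(
        mean=np.log(config.base_mean), sigma=config.base_sigma, size=config.n_genes
    )
    fold = np.ones(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in truth.up_genes:
        fold[gene_pos[g]] = 2.0**config.lfc
    for g in truth.down_genes:
        fold[gene_pos[g]] = 2.0**-config.lfc

    n_case, n_control = cohort.n_case, cohort.n_control
    sf = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=n_case + n_control)
    cols, data = [], []
    for j in range(n_case):
        mu = base * fold * sf[j]
        data.append(_nb_draw(rng, mu, config.dispersion))
        cols.append(f"{cohort.name}_case_{j + 1}")
    for j in range(n_control):
        mu = base * sf[n_case + j]
        data.append(_nb_draw(rng, mu, config.dispersion))
        cols.append(f"{cohort.name}_control_{j + 1}")

    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=cols, name="group"
    )
    return ExpressionMatrix(values=values, groups=groups, unit="raw_counts"), truth


def simulate_methylome(
    config: SimulationConfig, truth: SimulationTruth
) -> MethylationTable:
    """Probe table with beta-distributed replicates and planted shifts.

    One probe per gene plus ``multi_gene_probes`` extra probes annotated to
    two genes of the same planted status (joined with ';') to exercise the
    gene-mapping path without contaminating the truth sets.  Group means
    and a Welch p are computed from 7 case vs 5 control replicate betas.
    """
    rng = component_rng(config.seed, "methylome")
    genes = config.gene_ids()
    kappa = config.beta_concentration

    def status(g: str) -> str:
        if g in truth.hyper_genes:
            return "hyper"
        if g in truth.hypo_genes:
            return "hypo"
        return "null"

    def draw_row(gene_field: str, st: str) -> dict:
        # keep both group means (and the Beta parameters) inside (0, 1)
        lo = 0.05 + max(config.delta_beta, 0.0)
        b0 = rng.uniform(lo, 0.95 - max(config.delta_beta, 0.0))
        if st == "hyper":
            b_case = b0 + config.delta_beta
        elif st == "hypo":
            b_case = b0 - config.delta_beta
        else:
            b_case = b0
        if not (0 < b_case < 1 and 0 < b0 < 1):
            raise ValueError("beta parameters leave [0,1]; lower delta_beta")
        case = rng.beta(b_case * kappa, (1 - b_case) * kappa, size=config.meth_case_n)
        control = rng.beta(b0 * kappa, (1 - b0) * kappa, size=config.meth_control_n)
        row = {"genes": gene_field}
        for i, v in enumerate(case):
            row[f"case_{i + 1}"] = v
        for i, v in enumerate(control):
            row[f"control_{i + 1}"] = v
        return row

    rows = [draw_row(g, status(g)) for g in genes]

    # extra multi-gene probes: pair genes sharing a status
    by_status: dict[str, list[str]] = {"hyper": [], "hypo": [], "null": []}
    for g in genes:
        by_status[status(g)].append(g)
    pairs = []
    for st in ("hyper", "hypo", "null"):
        pool = by_status[st]
        for i in range(0, len(pool) - 1, 2):
            pairs.append((pool[i], pool[i + 1], st))
    rng.shuffle(pairs)
    for g1, g2, st in pairs[: config.multi_gene_probes]:
        rows.append(draw_row(f"{g1};{g2}", st))

    table = pd.DataFrame(rows)
    table.insert(0, "probe", [f"cg{i:07d}" for i in range(len(table))])
    case_cols = [f"case_{i + 1}" for i in range(config.meth_case_n)]
    control_cols = [f"control_{i + 1}" for i in range(config.meth_control_n)]
    return compute_delta_beta(table, case_cols=case_cols, control_cols=control_cols)


def simulate_validation_set(
    config: SimulationConfig, truth: SimulationTruth
) -> ExpressionMatrix:
    """Continuous (log-intensity) validation cohort preserving directions.

    Case samples are split into dysplasia / no_dysplasia subgroups; planted
    up genes are shifted +lfc in cases, down genes -lfc, on a normal noise
    background.
    """
    rng = component_rng(config.seed, "validation")
    genes = config.gene_ids()
    mu = rng.normal(5.0, 1.0, size=config.n_genes)
    shift = np.zeros(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in truth.up_genes:
        shift[gene_pos[g]] = config.lfc
    for g in truth.down_genes:
        shift[gene_pos[g]] = -config.lfc

    n_case, n_control = config.n_val_case, config.n_val_control
    cols, data, subgroup = [], [], []
    for j in range(n_case):
        data.append(rng.normal(mu + shift, config.val_noise_sd))
        cols.append(f"val_case_{j + 1}")
        subgroup.append("dysplasia" if j < n_case // 2 else "no_dysplasia")
    for j in range(n_control):
        data.append(rng.normal(mu, config.val_noise_sd))
        cols.append(f"val_control_{j + 1}")
        subgroup.append("na")

    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=cols, name="group"
    )
    return ExpressionMatrix(
        values=values,
        groups=groups,
        unit="log_intensity",
        subgroups=pd.Series(subgroup, index=cols, name="subgroup"),
    )


def simulate_cell_matrix(
    config: SimulationConfig,
    truth: SimulationTruth,
    patient: int = 0,
) -> CellMatrix:
    """Sparse genes x spots counts with labelled types and planted QC violators.

    Genes in a type's program have ``program_fold`` times the baseline mean
    in that type's spots.  Mito-prefixed genes are added on top of the
    bulk gene universe at a level targeting ``mito_target_fraction`` of
    counts.  A ``qc_violation_frac`` fraction of spots is planted to
    violate QC (half with < 200 detected features, half with > 10% mito);
    their ids are recorded in ``truth.qc_violators[patient]``.
    """
    for ct in truth.celltype_program:
        if ct not in config.celltypes:
            raise ValueError(f"unknown cell type in program: {ct!r}")
    rng = component_rng(config.seed, "cells", patient)
    bulk_genes = config.gene_ids()
    mito_genes = [f"{config.mito_prefix}{i + 1}" for i in range(config.n_mito)]
    genes = bulk_genes + mito_genes
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    base = np.full(n_genes, config.cell_base_mean)
    # mito level chosen so the expected mito fraction is mito_target_fraction
    non_mito_total = config.cell_base_mean * len(bulk_genes)
    target = config.mito_target_fraction
    base[len(bulk_genes) :] = target * non_mito_total / ((1 - target) * config.n_mito)

    spot_ids, labels, columns = [], [], []
    for ct in config.celltypes:
        mean = base.copy()
        for g in truth.celltype_program.get(ct, ()):
            mean[gene_pos[g]] *= config.program_fold
        for j in range(config.spots_per_type):
            spot = f"p{patient}_{ct}_{j + 1}"
            columns.append(rng.poisson(mean))
            spot_ids.append(spot)
            labels.append(ct)

    counts = np.column_stack(columns)

    # plant QC violators
    n_spots = len(spot_ids)
    n_violate = int(round(config.qc_violation_frac * n_spots))
    violators = list(rng.choice(n_spots, size=n_violate, replace=False)) if n_violate else []
    half = len(violators) // 2
    for k, s in enumerate(violators):
        if k < half or len(violators) == 1:
            # low-feature spot: keep at most 150 genes non-zero
            keep = rng.choice(n_genes, size=150, replace=False)
            mask = np.ones(n_genes, dtype=bool)
            mask[keep] = False
            counts[mask, s] = 0
        else:
            # high-mito spot: inflate mito counts to ~20% of the total
            total = counts[: len(bulk_genes), s].sum()
            counts[len(bulk_genes) :, s] = rng.poisson(
                0.25 * total / config.n_mito, size=config.n_mito
            )
    truth.qc_violators[patient] = sorted(spot_ids[s] for s in violators)

    return CellMatrix(
        counts=sparse.csr_matrix(counts),
        genes=pd.Index(genes),
        spots=pd.Index(spot_ids),
        labels=pd.Series(labels, index=spot_ids, name="cell_type"),
        mito_prefix=config.mito_prefix,
    )
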