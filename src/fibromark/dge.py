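"""Per-cohort differential expression with bootstrap stability selection.

Small OSF cohorts (down to n=2 per group) make single-shot differential
calls fragile.  Besides thresholded calling (|log2FC| >= 1 with BH-FDR or
raw p <= 0.05), this module implements a bootstrap stability framework:
samples are resampled with replacement within the case and control groups,
the DE test is re-run in each iteration, and each gene receives a stability
score -- the proportion of iterations in which it was called differentially
expressed.  Genes exceeding a stability threshold (default 0.6) are
retained as robust.

The DE engine is pluggable.  The default is a Welch t-test on
log2(CPM + 1); an alternative negative-binomial Wald test with
method-of-moments dispersion is provided.  Gene lengths are not modelled,
so CPM stands in for TPM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import component_rng

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "StabilityProfile",
    "normalize_log_expression",
    "de_test",
    "call_degs",
    "bootstrap_stability",
]

CASE = "case"
CONTROL = "control"
_ENGINES = ("welch", "nb_wald")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with case/control labels.

    ``unit`` is ``raw_counts`` for integer read counts or ``log_intensity``
    for anything already on a log scale (log2(CPM+1), microarray log
    ratios/intensities).
    """

    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> {"case", "control"}
    unit: str = "raw_counts"
    subgroups: pd.Series | None = None  # optional finer case labels

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing[:5]}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be case/control, got {sorted(bad)}")
        if self.unit not in ("raw_counts", "log_intensity"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit == "raw_counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def n_per_group(self) -> tuple[int, int]:
        return (
            int((self.groups == CASE).sum()),
            int((self.groups == CONTROL).sum()),
        )


@dataclass
class DEResult:
    """Per-gene DE table: log2_fc (case over control), p, BH q, call."""

    table: pd.DataFrame  # columns: log2_fc, p_value, q_value, call

    def __post_init__(self) -> None:
        required = {"log2_fc", "p_value", "q_value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index


@dataclass
class StabilityProfile:
    """Bootstrap stability scores: per-gene fraction of significant iterations."""

    table: pd.DataFrame  # columns: stability_score, retained
    n_iterations: int
    threshold: float
    comparator: str

    @property
    def retained_genes(self) -> set[str]:
        return set(self.table.index[self.table["retained"]])


def _cpm(counts: np.ndarray, colsums: np.ndarray | None = None) -> np.ndarray:
    if colsums is None:
        colsums = counts.sum(axis=0)
    return counts / colsums * 1e6


def normalize_log_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) per-library normalization of a raw count matrix."""
    if matrix.unit != "raw_counts":
        raise ValueError("normalize_log_expression expects unit='raw_counts'")
    counts = matrix.values.to_numpy(dtype=float)
    colsums = counts.sum(axis=0)
    if (colsums == 0).any():
        bad = matrix.samples[colsums == 0].tolist()
        raise ValueError(f"zero-total sample(s): {bad}")
    logm = np.log2(_cpm(counts, colsums) + 1.0)
    return ExpressionMatrix(
        values=pd.DataFrame(logm, index=matrix.genes, columns=matrix.samples),
        groups=matrix.groups.copy(),
        unit="log_intensity",
        subgroups=None if matrix.subgroups is None else matrix.subgroups.copy(),
    )


def _welch_arrays(
    case: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t on rows; zero-variance-in-both rows get p=1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        t = np.asarray(res.statistic, dtype=float)
    both_const = (case.var(axis=1) == 0) & (control.var(axis=1) == 0)
    p = np.where(both_const | ~np.isfinite(p), np.where(both_const, 1.0, p), p)
    p[~np.isfinite(p)] = 1.0
    t[~np.isfinite(t)] = 0.0
    return t, p


def _lfc_from_cpm(case_cpm: np.ndarray, control_cpm: np.ndarray) -> np.ndarray:
    # +1 pseudocount on group-mean CPM keeps the ratio finite.
    return np.log2((case_cpm.mean(axis=1) + 1.0) / (control_cpm.mean(axis=1) + 1.0))


def _nb_wald(case_counts: np.ndarray, control_counts: np.ndarray) -> np.ndarray:
    """NB Wald p-values with a method-of-moments common dispersion per gene.

    Works on CPM-scaled counts so library size differences do not masquerade
    as expression changes.  Var(log mu_hat) ~ (1/mu + alpha)/n by the delta
    method under NB(mu, alpha).
    """
    case = _cpm(case_counts)
    control = _cpm(control_counts)
    n1, n2 = case.shape[1], control.shape[1]
    m1 = case.mean(axis=1) + 0.5
    m2 = control.mean(axis=1) + 0.5
    # pooled excess-Poisson dispersion, floored at 0
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    alpha1 = np.clip((v1 - m1) / m1**2, 0.0, None)
    alpha2 = np.clip((v2 - m2) / m2**2, 0.0, None)
    alpha = (alpha1 * (n1 - 1) + alpha2 * (n2 - 1)) / (n1 + n2 - 2)
    beta = np.log(m1 / m2)
    se = np.sqrt((1.0 / m1 + alpha) / n1 + (1.0 / m2 + alpha) / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_const = (case_counts.var(axis=1) == 0) & (control_counts.var(axis=1) == 0)
    p = np.where(both_const | ~np.isfinite(p), 1.0, p)
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    return multipletests(p, method="fdr_bh")[1]


def de_test(matrix: ExpressionMatrix, engine: str = "welch") -> DEResult:
    """Two-group differential expression, one row per gene.

    Raw counts are normalized internally (log2(CPM+1) for the Welch engine,
    CPM scaling for the NB Wald engine); log-intensity input is tested
    as-is by the Welch engine.
    """
    if engine not in _ENGINES:
        raise ValueError(f"engine must be one of {_ENGINES}")
    n_case, n_control = matrix.n_per_group()
    if n_case < 2 or n_control < 2:
        raise ValueError(
            f"need >=2 samples per group, got case={n_case} control={n_control}"
        )
    raw = matrix.values.to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("expression matrix contains NaNs")
    case_cols = matrix.group_columns(CASE)
    control_cols = matrix.group_columns(CONTROL)

    if matrix.unit == "raw_counts":
        counts = raw
        cpm = _cpm(counts)
        idx = {s: i for i, s in enumerate(matrix.samples)}
        ci = [idx[s] for s in case_cols]
        gi = [idx[s] for s in control_cols]
        lfc = _lfc_from_cpm(cpm[:, ci], cpm[:, gi])
        if engine == "welch":
            logm = np.log2(cpm + 1.0)
            _, p = _welch_arrays(logm[:, ci], logm[:, gi])
        else:
            p = _nb_wald(counts[:, ci], counts[:, gi])
    else:
        if engine == "nb_wald":
            raise ValueError("nb_wald engine requires raw counts")
        case = matrix.values[case_cols].to_numpy(dtype=float)
        control = matrix.values[control_cols].to_numpy(dtype=float)
        _, p = _welch_arrays(case, control)
        # de-log (base 2) to compute the fold change on the linear scale
        lfc = np.log2(
            (np.exp2(case).mean(axis=1)) / (np.exp2(control).mean(axis=1))
        )

    q = bh_adjust(p)
    table = pd.DataFrame(
        {"log2_fc": lfc, "p_value": p, "q_value": q}, index=matrix.genes
    )
    table["call"] = "ns"
    up, down = call_degs(DEResult(table), lfc=1.0, alpha=0.05, criterion="fdr")
    table.loc[sorted(up), "call"] = "up"
    table.loc[sorted(down), "call"] = "down"
    return DEResult(table)


def call_degs(
    result: DEResult,
    lfc: float = 1.0,
    alpha: float = 0.05,
    criterion: str = "fdr",
) -> tuple[set[str], set[str]]:
    """Thresholded up/down calls.

    up = {log2_fc >= lfc and sig <= alpha}, down symmetric; ``criterion``
    chooses the significance column: BH-FDR (default) or raw p for the
    small-cohort relaxed mode.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if criterion not in ("fdr", "raw_p"):
        raise ValueError("criterion must be 'fdr' or 'raw_p'")
    t = result.table
    if t.empty:
        return set(), set()
    sig = t["q_value"] if criterion == "fdr" else t["p_value"]
    up = set(t.index[(t["log2_fc"] >= lfc) & (sig <= alpha)])
    down = set(t.index[(t["log2_fc"] <= -lfc) & (sig <= alpha)])
    return up, down


def bootstrap_stability(
    matrix: ExpressionMatrix,
    B: int = 500,
    threshold: float = 0.6,
    comparator: str = "gt",
    criterion: str = "fdr",
    lfc: float = 1.0,
    alpha: float = 0.05,
    engine: str = "welch",
    seed: int = 0,
) -> StabilityProfile:
    """Bootstrap stability selection of differentially expressed genes.

    Each of the B iterations resamples sample indices with replacement
    independently within the case and within the control group (group sizes
    preserved), reruns the DE test and the threshold calls, and counts for
    every gene whether it was called up or down.  stability_score(g) is
    that count divided by B; a gene is retained when its score exceeds
    ``threshold`` (strictly for comparator='gt', inclusively for 'ge').

    Degenerate draws in which a group collapses onto one distinct sample
    are kept: such genes show zero within-group variance and simply count
    as not significant in that iteration.
    """
    if B <= 0:
        raise ValueError(f"B must be positive, got {B}")
    if comparator not in ("gt", "ge"):
        raise ValueError("comparator must be 'gt' or 'ge'")
    n_case, n_control = matrix.n_per_group()
    if n_case < 2 or n_control < 2:
        raise ValueError("need >=2 samples per group")
    if engine not in _ENGINES:
        raise ValueError(f"engine must be one of {_ENGINES}")

    idx = {s: i for i, s in enumerate(matrix.samples)}
    ci = np.array([idx[s] for s in matrix.group_columns(CASE)])
    gi = np.array([idx[s] for s in matrix.group_columns(CONTROL)])

    raw = matrix.values.to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("expression matrix contains NaNs")
    if matrix.unit == "raw_counts":
        cpm = _cpm(raw)
        logm = np.log2(cpm + 1.0)
        counts = raw
    else:
        if engine == "nb_wald":
            raise ValueError("nb_wald engine requires raw counts")
        # already log scale: fold changes computed on the de-logged values
        cpm = np.exp2(raw)
        logm = raw
        counts = None

    hits = np.zeros(len(matrix.genes), dtype=np.int64)
    for i in range(B):
        rng = component_rng(seed, "bootstrap", i)
        bci = rng.choice(ci, size=len(ci), replace=True)
        bgi = rng.choice(gi, size=len(gi), replace=True)
        # CPM is per-sample, so column resampling reuses precomputed columns
        lfc_i = np.log2(
            (cpm[:, bci].mean(axis=1) + 1.0) / (cpm[:, bgi].mean(axis=1) + 1.0)
        )
        if engine == "welch":
            _, p = _welch_arrays(logm[:, bci], logm[:, bgi])
        else:
            p = _nb_wald(counts[:, bci], counts[:, bgi])
        sig = bh_adjust(p) if criterion == "fdr" else p
        hits += ((np.abs(lfc_i) >= lfc) & (sig <= alpha)).astype(np.int64)

    score = hits / B
    retained = score > threshold if comparator == "gt" else score >= threshold
    table = pd.DataFrame(
        {"stability_score": score, "retained": retained}, index=matrix.genes
    )
    return StabilityProfile(
        table=table, n_iterations=B, threshold=threshold, comparator=comparator
    )
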