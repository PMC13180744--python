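"""External-cohort validation of candidate markers.

Per-gene discriminative power is measured by the ROC AUC with cases as
the positive class; AUC is the Mann-Whitney U statistic scaled by
n_case * n_control (ties counted 0.5), so AUC > 0.5 means higher
expression in cases.  Group-level log2 ratios, z-score matrices for
heatmaps, direction-concordance counts against the discovery signature,
and the downstream cell-fraction statistics (Spearman correlations among
cell types in cases, Mann-Whitney group tests) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dge import CASE, CONTROL, ExpressionMatrix

__all__ = [
    "AUCResult",
    "gene_auc",
    "auc_table",
    "group_log_ratio",
    "direction_concordance",
    "ConcordanceReport",
    "zscore_matrix",
    "fraction_stats",
]


@dataclass
class AUCResult:
    auc: float
    direction: str  # "case_high" | "control_high"
    n_case: int
    n_control: int


def gene_auc(values: np.ndarray, labels: np.ndarray) -> AUCResult:
    """ROC AUC of one gene's expression for case vs control.

    Equals U / (n_case * n_control) where U is the Mann-Whitney statistic
    for the case group; tied pairs count one half.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    case = values[labels == CASE]
    control = values[labels == CONTROL]
    if len(case) == 0 or len(control) == 0:
        raise ValueError(
            f"both classes required, got case={len(case)} control={len(control)}"
        )
    u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
    auc = float(u) / (len(case) * len(control))
    return AUCResult(
        auc=auc,
        direction="case_high" if auc >= 0.5 else "control_high",
        n_case=len(case),
        n_control=len(control),
    )


def auc_table(matrix: ExpressionMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene AUC over an expression matrix (rows: gene; auc, direction)."""
    labels = matrix.groups.to_numpy()
    use = matrix.genes if genes is None else [g for g in genes if g in matrix.genes]
    rows = {}
    vals = matrix.values
    for g in use:
        r = gene_auc(vals.loc[g].to_numpy(), labels)
        rows[g] = {"auc": r.auc, "direction": r.direction}
    return pd.DataFrame.from_dict(rows, orient="index")


def group_log_ratio(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> pd.Series:
    """Per-gene log2(mean case / mean control) on the linear scale.

    Data flagged log-scale is de-logged (2^x) before averaging so the
    ratio compares linear group means; ``pseudocount`` is added to both
    means to protect zero-count genes.
    """
    case_cols = matrix.group_columns(CASE)
    control_cols = matrix.group_columns(CONTROL)
    if not case_cols or not control_cols:
        raise ValueError("both groups must be non-empty")
    vals = matrix.values
    if matrix.unit == "log_intensity":
        vals = np.exp2(vals)
    m_case = vals[case_cols].mean(axis=1) + pseudocount
    m_control = vals[control_cols].mean(axis=1) + pseudocount
    if not (np.isfinite(m_case).all() and np.isfinite(m_control).all()):
        raise ValueError("non-finite group means")
    if (m_case <= 0).any() or (m_control <= 0).any():
        raise ValueError("group means must be positive (set a pseudocount)")
    return pd.Series(
        np.log2(m_case / m_control), index=matrix.genes, name="log2_ratio"
    )


@dataclass
class ConcordanceReport:
    n_concordant_up: int
    total_up: int
    n_concordant_down: int
    total_down: int
    table: pd.DataFrame  # per-gene: discovery_direction, validation_direction, concordant
    missing: list[str]

    @property
    def fraction_concordant(self) -> float:
        total = self.total_up + self.total_down
        if total == 0:
            return float("nan")
        return (self.n_concordant_up + self.n_concordant_down) / total


def direction_concordance(
    discovery: dict[str, str],
    validation: pd.DataFrame,
) -> ConcordanceReport:
    """Compare discovery direction (up/down) with validation AUC direction.

    ``discovery`` maps gene -> "up"/"down"; ``validation`` is an
    auc_table-style frame with a ``direction`` column.  A gene is
    concordant when up maps to case_high and down to control_high.  Gene
    ids are matched case-insensitively but exactly (no aliasing); genes
    absent from the validation table are listed under ``missing``.
    """
    val_dir = {str(g).upper(): d for g, d in validation["direction"].items()}
    rows, missing = [], []
    for gene, disc in discovery.items():
        if disc not in ("up", "down"):
            raise ValueError(f"discovery direction must be up/down, got {disc!r}")
        v = val_dir.get(str(gene).upper())
        if v is None:
            missing.append(gene)
            continue
        expected = "case_high" if disc == "up" else "control_high"
        rows.append((gene, disc, v, v == expected))
    table = pd.DataFrame(
        rows, columns=["gene", "discovery_direction", "validation_direction", "concordant"]
    ).set_index("gene")
    up = table[table["discovery_direction"] == "up"]
    down = table[table["discovery_direction"] == "down"]
    return ConcordanceReport(
        n_concordant_up=int(up["concordant"].sum()),
        total_up=len(up),
        n_concordant_down=int(down["concordant"].sum()),
        total_down=len(down),
        table=table,
        missing=missing,
    )


def zscore_matrix(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Row-standardise genes to mean 0, population sd 1 (heatmap scale).

    Zero-variance rows become all-zero and their gene ids are returned as
    the second element.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("need >=2 samples to z-score")
    vals = matrix.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (vals - mu) / sd
    z[flat, :] = 0.0
    out = pd.DataFrame(z, index=matrix.genes, columns=matrix.samples)
    return out, list(matrix.genes[flat])


def fraction_stats(
    fractions: pd.DataFrame,
    groups: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cell-fraction statistics downstream of deconvolution.

    ``fractions`` is cell types x samples.  Returns (1) the Spearman
    correlation matrix among cell types computed on case samples only --
    constant cell types are reported as missing (NaN), not zero -- and
    (2) a two-sided Mann-Whitney p per cell type comparing case vs
    control fractions.
    """
    groups = groups.reindex(fractions.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    case_cols = list(groups.index[groups == CASE])
    control_cols = list(groups.index[groups == CONTROL])
    if len(case_cols) < 3:
        raise ValueError("need >=3 case samples for the correlation matrix")

    case = fractions[case_cols]
    corr = case.T.corr(method="spearman")
    constant = case.nunique(axis=1) == 1
    for ct in fractions.index[constant]:
        corr.loc[ct, :] = np.nan
        corr.loc[:, ct] = np.nan
    for ct in fractions.index[~constant]:
        corr.loc[ct, ct] = 1.0

    pvals = {}
    for ct in fractions.index:
        a = fractions.loc[ct, case_cols].to_numpy(dtype=float)
        b = fractions.loc[ct, control_cols].to_numpy(dtype=float)
        if len(b) == 0:
            pvals[ct] = np.nan
        else:
            pvals[ct] = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
    return corr, pd.Series(pvals, name="mannwhitney_p")
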