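"""Cell-type enrichment of a gene set in spatial/single-cell spots.

Spots (10x Visium capture locations, potentially multi-cellular) carry a
cell-type label.  After QC (spots with fewer than 200 detected features or
more than 10% mitochondrial counts are removed; no upper feature cutoff,
deliberately, because multi-cellular spots legitimately run hot), counts
are library-size log-normalized, every gene is z-scored across all spots,
and a gene counts as "expressed" in a cell type when its mean z over that
type's spots is strictly positive.  Per cell type, Obs = number of
expressed genes from the query set (the DEGs), Exp = number of expressed
genes overall, and the enrichment score is

    raw = log2( (Obs / n_deg) / (Exp / n_genes) )

i.e. a ratio of expressed fractions (the literal log2(Obs/Exp), which is
non-positive whenever the query set is a subset of the universe, is
available behind ``mode="literal"``).  Raw scores are normalized to
[-1, 1] by dividing by the maximum absolute raw score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CellMatrix",
    "qc_filter",
    "expressed_gene_sets",
    "deg_enrichment_score",
]


@dataclass
class CellMatrix:
    """Genes x spots sparse counts with per-spot cell-type labels."""

    counts: sparse.csr_matrix  # genes x spots
    genes: pd.Index
    spots: pd.Index
    labels: pd.Series  # spot -> cell type
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        self.spots = pd.Index(self.spots)
        if self.counts.shape != (len(self.genes), len(self.spots)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        self.labels = self.labels.reindex(self.spots)
        if self.labels.isna().any():
            missing = self.spots[self.labels.isna()].tolist()
            raise ValueError(f"spots without cell-type label: {missing[:5]}")

    @property
    def mito_mask(self) -> np.ndarray:
        return np.asarray(self.genes.str.startswith(self.mito_prefix))

    def qc_metrics(self) -> pd.DataFrame:
        """Per-spot n_features (genes with count > 0), total counts, mito fraction."""
        csc = self.counts.tocsc()
        csc.eliminate_zeros()  # stored explicit zeros would inflate n_features
        n_features = np.diff(csc.indptr)  # nonzeros per spot column
        total = np.asarray(csc.sum(axis=0)).ravel()
        mito = np.asarray(csc[self.mito_mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        return pd.DataFrame(
            {"n_features": n_features, "total_counts": total, "mito_fraction": frac},
            index=self.spots,
        )

    def subset_spots(self, keep: np.ndarray) -> "CellMatrix":
        return CellMatrix(
            counts=self.counts[:, keep],
            genes=self.genes,
            spots=self.spots[keep],
            labels=self.labels.iloc[keep].copy(),
            mito_prefix=self.mito_prefix,
        )


def qc_filter(
    matrix: CellMatrix,
    min_features: int = 200,
    max_mito: float = 0.10,
) -> tuple[CellMatrix, dict]:
    """Remove low-quality spots.

    Keeps spots with n_features >= min_features and mito fraction
    <= max_mito (strict > removes; a fraction of exactly 0.10 is kept).
    There is no upper feature cutoff.  Returns the filtered matrix and a
    removal log.
    """
    qc = matrix.qc_metrics()
    low_feat = qc["n_features"] < min_features
    high_mito = qc["mito_fraction"] > max_mito
    keep = ~(low_feat | high_mito)
    if not keep.any():
        raise ValueError(
            "all spots removed by QC; summary: "
            f"median features {qc['n_features'].median()}, "
            f"median mito {qc['mito_fraction'].median():.3f}"
        )
    log = {
        "n_input": len(qc),
        "n_kept": int(keep.sum()),
        "removed_low_features": sorted(qc.index[low_feat].tolist()),
        "removed_high_mito": sorted(qc.index[high_mito].tolist()),
        "min_features": min_features,
        "max_mito": max_mito,
    }
    return matrix.subset_spots(keep.to_numpy()), log


def _log_normalize(counts: sparse.csr_matrix, scale: float = 1e4) -> np.ndarray:
    """log1p of counts scaled to a common library size per spot."""
    dense = np.asarray(counts.todense(), dtype=float)
    totals = dense.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(dense / totals * scale)


def expressed_gene_sets(
    matrix: CellMatrix,
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-cell-type expressed gene sets via cross-spot z-scoring.

    Each gene is z-scored across all spots of the (QC-filtered,
    log-normalized) matrix with population sd; per cell type the mean z
    over that type's spots is taken; expressed means mean z strictly
    positive.  Returns (type -> expressed set, zero-variance genes) --
    zero-variance genes are excluded from every set.
    """
    if len(matrix.spots) < 2:
        raise ValueError("need >= 2 spots")
    types = sorted(matrix.labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    ln = _log_normalize(matrix.counts)
    mu = ln.mean(axis=1, keepdims=True)
    sd = ln.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (ln - mu) / sd

    labels = matrix.labels.to_numpy()
    gene_arr = matrix.genes.to_numpy()
    sets: dict[str, set[str]] = {}
    for t in types:
        cols = labels == t
        mean_z = z[:, cols].mean(axis=1)
        sets[t] = set(gene_arr[(mean_z > 0) & ~flat])
    zero_var = set(gene_arr[flat])
    return sets, zero_var


def deg_enrichment_score(
    expressed: dict[str, set[str]],
    deg_set: set[str],
    universe: set[str],
    mode: str = "fraction",
    normalization: str = "max_abs",
) -> pd.DataFrame:
    """Per-cell-type Obs/Exp enrichment of a gene set.

    ``universe`` is the set of genes that survived z-scoring.  For each
    cell type, Obs is the number of query genes expressed there and Exp
    the number of universe genes expressed there.  ``mode="fraction"``
    scores log2((Obs/n_deg)/(Exp/n_genes)); ``mode="literal"`` scores
    log2(Obs/Exp).  Zero counts get a half-count continuity correction.
    ``normalization``: "max_abs" divides by max |raw| (all-zero maps to
    zeros); "minmax" maps the raw range affinely onto [-1, 1].
    """
    if mode not in ("fraction", "literal"):
        raise ValueError("mode must be 'fraction' or 'literal'")
    if normalization not in ("max_abs", "minmax"):
        raise ValueError("normalization must be 'max_abs' or 'minmax'")
    universe = set(universe)
    deg_in = set(deg_set) & universe
    if not deg_in:
        raise ValueError("deg_set is empty (or disjoint from the universe)")
    n_deg = len(deg_in)
    n_genes = len(universe)

    rows = []
    for ct in sorted(expressed):
        expr = expressed[ct] & universe
        obs = len(deg_in & expr)
        exp = len(expr)
        obs_c = obs if obs > 0 else 0.5
        exp_c = exp if exp > 0 else 0.5
        if mode == "fraction":
            raw = np.log2((obs_c / n_deg) / (exp_c / n_genes))
        else:
            raw = np.log2(obs_c / exp_c)
        rows.append((ct, obs, exp, raw))
    table = pd.DataFrame(
        rows, columns=["cell_type", "obs", "exp", "raw_score"]
    ).set_index("cell_type")
    table["n_deg"] = n_deg
    table["n_genes"] = n_genes

    raw = table["raw_score"].to_numpy()
    if normalization == "max_abs":
        m = np.max(np.abs(raw))
        norm = raw / m if m > 0 else np.zeros_like(raw)
    else:
        lo, hi = raw.min(), raw.max()
        norm = np.zeros_like(raw) if hi == lo else 2 * (raw - lo) / (hi - lo) - 1
    table["normalized_score"] = norm
    return table
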