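"""Probe-level delta-beta computation and gene-level methylation calls.

Methylation is summarised per CpG probe as a beta value in [0, 1].  The
effect measure is delta-beta = mean beta in cases (OSF) minus mean beta in
controls: positive means hypermethylated in disease.  Probes passing
|delta-beta| >= 0.1 with p <= 0.05 (raw p by default -- FDR left a
negligible list in the source data, so raw p is the documented choice;
an FDR mode is available) are aggregated to genes: a gene is hyper- or
hypomethylated if ANY of its probes qualifies.  Probes annotated to
several genes carry a delimiter-joined gene field and contribute to each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust

__all__ = ["MethylationTable", "DMGCall", "compute_delta_beta", "classify_dmgs"]

_REQUIRED = ["probe", "genes", "beta_case_mean", "beta_control_mean", "p_value"]


@dataclass
class MethylationTable:
    """Per-probe table: probe, genes, group beta means, delta_beta, p (, q)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"methylation table missing columns {missing}")
        t = self.table
        for col in ("beta_case_mean", "beta_control_mean"):
            bad = t.loc[(t[col] < 0) | (t[col] > 1), "probe"]
            if len(bad):
                raise ValueError(
                    f"beta values outside [0,1] for probe(s) {bad.tolist()[:5]}"
                )
        if "delta_beta" in t.columns:
            resid = (t["delta_beta"] - (t["beta_case_mean"] - t["beta_control_mean"])).abs()
            if (resid > 1e-12).any():
                raise ValueError("delta_beta inconsistent with group means")


@dataclass
class DMGCall:
    """Gene-level methylation call sets; ambiguous genes appear in both."""

    hyper: set[str] = field(default_factory=set)
    hypo: set[str] = field(default_factory=set)
    ambiguous: set[str] = field(default_factory=set)
    probe_table: pd.DataFrame | None = None  # per-probe audit of the calls


def compute_delta_beta(
    table: pd.DataFrame,
    case_cols: list[str] | None = None,
    control_cols: list[str] | None = None,
) -> MethylationTable:
    """Fill delta_beta (= case mean - control mean) on a probe table.

    Two input shapes are accepted: precomputed group means with a p_value
    column, or per-replicate beta columns (``case_cols`` / ``control_cols``)
    from which means are taken and a two-sided Welch p computed per probe.
    """
    t = table.copy()
    if case_cols is not None or control_cols is not None:
        if not case_cols or not control_cols:
            raise ValueError("both case_cols and control_cols are required")
        case = t[case_cols].to_numpy(dtype=float)
        control = t[control_cols].to_numpy(dtype=float)
        bad_rows = ((case < 0) | (case > 1)).any(axis=1) | (
            (control < 0) | (control > 1)
        ).any(axis=1)
        if bad_rows.any():
            bad = t.loc[bad_rows, "probe"]
            raise ValueError(f"replicate betas outside [0,1]: {bad.tolist()[:5]}")
        t["beta_case_mean"] = case.mean(axis=1)
        t["beta_control_mean"] = control.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(case, control, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0
        t["p_value"] = p
    t["delta_beta"] = t["beta_case_mean"] - t["beta_control_mean"]
    return MethylationTable(t)


def classify_dmgs(
    table: MethylationTable,
    effect: float = 0.1,
    alpha: float = 0.05,
    criterion: str = "raw_p",
    delimiter: str = ";",
) -> DMGCall:
    """Call hyper-/hypomethylated genes from a probe table.

    A probe is hyper-significant when delta_beta >= effect and its
    significance value is <= alpha; hypo-significant symmetrically at
    -effect.  Multi-gene annotations are split on ``delimiter`` and every
    named gene counts.  A gene with at least one qualifying probe in each
    direction is ambiguous: it stays in both sets and is flagged.
    """
    if effect <= 0:
        raise ValueError(f"effect must be positive, got {effect}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if criterion not in ("raw_p", "fdr"):
        raise ValueError("criterion must be 'raw_p' or 'fdr'")

    t = table.table.copy()
    if t.empty:
        return DMGCall(probe_table=t)
    if "delta_beta" not in t.columns:
        t["delta_beta"] = t["beta_case_mean"] - t["beta_control_mean"]
    if criterion == "fdr":
        sig = t["q_value"] if "q_value" in t.columns else pd.Series(
            bh_adjust(t["p_value"].to_numpy()), index=t.index
        )
    else:
        sig = t["p_value"]

    hyper_probe = (t["delta_beta"] >= effect) & (sig <= alpha)
    hypo_probe = (t["delta_beta"] <= -effect) & (sig <= alpha)
    t["probe_call"] = np.select(
        [hyper_probe, hypo_probe], ["hyper", "hypo"], default="ns"
    )

    hyper: set[str] = set()
    hypo: set[str] = set()
    for genes_field, call in zip(t["genes"], t["probe_call"]):
        if call == "ns":
            continue
        for g in str(genes_field).split(delimiter):
            g = g.strip()
            if not g:
                continue
            (hyper if call == "hyper" else hypo).add(g)
    ambiguous = hyper & hypo
    return DMGCall(hyper=hyper, hypo=hypo, ambiguous=ambiguous, probe_table=t)
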