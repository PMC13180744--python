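"""Direction-consistent transcriptome-methylome integration.

Promoter hypomethylation generally permits expression and hypermethylation
represses it, so a credible epigenetically-driven biomarker is a gene that
is upregulated AND hypomethylated, or downregulated AND hypermethylated.
The integrated signature is (up ∩ hypo) ∪ (down ∩ hyper).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .methylome import DMGCall

__all__ = ["IntegratedSignature", "integrate_signature"]


@dataclass
class IntegratedSignature:
    """Alphabetically ordered signature with direction/methylation arms."""

    table: pd.DataFrame  # index: gene; columns: direction, methylation_state,
    # ambiguous_methylation + optional annotations

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def up_hypo(self) -> set[str]:
        t = self.table
        return set(t.index[(t["direction"] == "up") & (t["methylation_state"] == "hypo")])

    @property
    def down_hyper(self) -> set[str]:
        t = self.table
        return set(
            t.index[(t["direction"] == "down") & (t["methylation_state"] == "hyper")]
        )

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "up_hypo": sorted(self.up_hypo),
            "down_hyper": sorted(self.down_hyper),
        }


def integrate_signature(
    up: set[str],
    down: set[str],
    dmg: DMGCall,
    annotations: pd.DataFrame | None = None,
) -> IntegratedSignature:
    """(up ∩ hypo) ∪ (down ∩ hyper), annotated and alphabetically ordered.

    ``annotations`` (optional, indexed by gene) is carried through for the
    member genes; absent genes get nulls.  Genes whose methylation call is
    ambiguous (probes in both directions) can satisfy either arm and are
    flagged; a gene satisfying both arms via ambiguity is listed once per
    arm.
    """
    up = set(up)
    down = set(down)
    both_dirs = up & down
    if both_dirs:
        raise ValueError(f"genes in both up and down inputs: {sorted(both_dirs)[:5]}")

    rows = []
    for g in sorted(up & dmg.hypo):
        rows.append((g, "up", "hypo", g in dmg.ambiguous))
    for g in sorted(down & dmg.hyper):
        rows.append((g, "down", "hyper", g in dmg.ambiguous))
    rows.sort(key=lambda r: (r[0], r[1]))

    table = pd.DataFrame(
        rows, columns=["gene", "direction", "methylation_state", "ambiguous_methylation"]
    ).set_index("gene")
    if annotations is not None and not table.empty:
        extra = annotations.reindex(table.index)
        for col in extra.columns:
            table[col] = extra[col]
    return IntegratedSignature(table)
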