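"""Multi-cohort consensus of directional DEG calls and overlap statistics.

A gene becomes a consensus biomarker candidate when it is called in the
same direction in at least ``min_freq`` cohorts (default 2, i.e. present
in at least two of the three discovery datasets).  Genes called up in one
cohort and down in another are direction conflicts: they are excluded from
both consensus sets and reported explicitly, never silently merged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "DirectionalGeneSet",
    "ConsensusResult",
    "frequency_consensus",
    "overlap_percentage",
]


@dataclass
class DirectionalGeneSet:
    """Up/down gene calls from one cohort; the two sets must be disjoint."""

    cohort: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        both = self.up & self.down
        if both:
            raise ValueError(
                f"cohort {self.cohort}: genes in both up and down: {sorted(both)[:5]}"
            )


@dataclass
class ConsensusResult:
    up: set[str]
    down: set[str]
    conflicts: set[str]
    min_freq: int
    n_cohorts: int

    def to_dict(self) -> dict:
        return {
            "up": sorted(self.up),
            "down": sorted(self.down),
            "conflicts": sorted(self.conflicts),
            "min_freq": self.min_freq,
            "n_cohorts": self.n_cohorts,
        }


def frequency_consensus(
    sets: list[DirectionalGeneSet], min_freq: int = 2
) -> ConsensusResult:
    """Frequency-based consensus across cohorts.

    A gene enters the up-consensus when it appears in the up set of at
    least ``min_freq`` cohorts (counting direction-agnostic appearances for
    the frequency, direction-consistent membership for the set); symmetric
    for down.  A gene reaching the frequency cutoff with discordant
    directions across cohorts goes to ``conflicts``.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 cohorts")
    if min_freq > len(sets):
        raise ValueError(
            f"min_freq={min_freq} exceeds number of cohorts ({len(sets)})"
        )
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")

    up_count: Counter[str] = Counter()
    down_count: Counter[str] = Counter()
    for s in sets:
        up_count.update(s.up)
        down_count.update(s.down)

    all_genes = set(up_count) | set(down_count)
    up, down, conflicts = set(), set(), set()
    for g in all_genes:
        freq = up_count[g] + down_count[g]
        if freq < min_freq:
            continue
        if up_count[g] and down_count[g]:
            conflicts.add(g)
        elif up_count[g] >= min_freq:
            up.add(g)
        elif down_count[g] >= min_freq:
            down.add(g)
        # consistent direction but below min_freq in that direction cannot
        # happen once freq >= min_freq and the other direction is empty
    return ConsensusResult(
        up=up, down=down, conflicts=conflicts, min_freq=min_freq, n_cohorts=len(sets)
    )


def overlap_percentage(n_common: int, n_reference: int) -> float:
    """100 * n_common / n_reference, half-away-from-zero to one decimal.

    Matches printed overlap percentages such as 64.8 for 214/330.
    """
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    if not (0 <= n_common <= n_reference):
        raise ValueError(
            f"n_common must be in [0, n_reference], got {n_common}/{n_reference}"
        )
    pct = Decimal(100 * n_common) / Decimal(n_reference)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
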