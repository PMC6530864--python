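"""Per-reaction cost arithmetic for genotyping kits.

A genotyping run consumes two kits — the allele-specific assay mix and the
universal master mix — each sold in a minimum orderable amount good for a
known number of reactions.  The per-reaction cost is simply each kit's price
divided by its reaction count, summed:

    raw = assay_price / assay_reactions + mastermix_price / mastermix_reactions

Arithmetic is exact decimal, and the displayed figure is rounded half-up to
the cent; rankings always use the raw (unrounded) value, so rounding can
never reorder platforms.  DNA-extraction cost is deliberately excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "CostSpec",
    "cost_per_reaction",
    "rank_platforms",
    "reference_cost_specs",
    "read_cost_specs",
]


@dataclass(frozen=True)
class CostSpec:
    """Kit pricing for one platform.

    ``reaction_volume_ul`` is metadata only (costs here are quoted per 5 ul
    reaction); it never enters the arithmetic.
    """

    platform_id: str
    assay_price: float
    assay_reactions: int
    mastermix_price: float
    mastermix_reactions: int
    reaction_volume_ul: float = 5.0

    def __post_init__(self) -> None:
        if self.assay_price < 0 or self.mastermix_price < 0:
            raise ValueError(f"{self.platform_id}: prices must be non-negative")
        if self.assay_reactions <= 0 or self.mastermix_reactions <= 0:
            raise ValueError(f"{self.platform_id}: reaction counts must be positive")
        if self.reaction_volume_ul <= 0:
            raise ValueError(f"{self.platform_id}: reaction volume must be positive")


def cost_per_reaction(spec: CostSpec) -> tuple[float, float]:
    """Return (raw, rounded-to-cent) cost per reaction in the kit currency.

    Division is exact decimal and rounding is half-up, matching how vendors
    quote per-reaction prices.
    """
    raw = Decimal(str(spec.assay_price)) / spec.assay_reactions + Decimal(
        str(spec.mastermix_price)
    ) / spec.mastermix_reactions
    rounded = raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(raw), float(rounded)


def rank_platforms(specs: Sequence[CostSpec]) -> pd.DataFrame:
    """Platforms ordered cheapest-first by raw per-reaction cost.

    The sort is stable: platforms with identical raw cost keep input order.
    """
    if not specs:
        raise ValueError("at least one cost spec required")
    rows = []
    for spec in specs:
        raw, rounded = cost_per_reaction(spec)
        rows.append(
            {
                "platform_id": spec.platform_id,
                "raw_cost": raw,
                "cost_per_reaction": rounded,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("raw_cost", kind="stable").reset_index(drop=True)


def reference_cost_specs() -> tuple[CostSpec, CostSpec, CostSpec]:
    """Published list prices of the three chemistries (5 ul reactions).

    TaqMan: $259 assay mix / 2,000 reactions plus $554 master mix / 2,000.
    KASP: $64.20 assay mix / 5,000 plus $1,382.50 master mix / 10,000.
    rhAmp: $75.60 assay mix / 5,000 plus $1,038.60 master mix / 10,000.
    """
    return (
        CostSpec("TaqMan", 259.0, 2000, 554.0, 2000),
        CostSpec("KASP", 64.2, 5000, 1382.5, 10000),
        CostSpec("rhAmp", 75.6, 5000, 1038.6, 10000),
    )


def read_cost_specs(path: str | Path) -> list[CostSpec]:
    """Read cost specs from a CSV with the CostSpec field names as columns."""
    frame = pd.read_csv(path)
    required = [
        "platform_id",
        "assay_price",
        "assay_reactions",
        "mastermix_price",
        "mastermix_reactions",
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column {missing[0]!r}")
    specs = []
    for r in frame.itertuples(index=False):
        kwargs = dict(
            platform_id=str(r.platform_id),
            assay_price=float(r.assay_price),
            assay_reactions=int(r.assay_reactions),
            mastermix_price=float(r.mastermix_price),
            mastermix_reactions=int(r.mastermix_reactions),
        )
        if "reaction_volume_ul" in frame.columns:
            kwargs["reaction_volume_ul"] = float(r.reaction_volume_ul)
        specs.append(CostSpec(**kwargs))
    return specs
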