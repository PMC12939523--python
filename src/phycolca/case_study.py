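"""Product- and corporate-level use of the carbon-negative colorant.

Product level: the cradle-to-gate footprint of a 100 g bag of mixed-colour
chocolate dragees is raw-material emissions, a production overhead taken
as a fraction of the raw-material footprint (default 30%, a deliberately
conservative stand-in for missing factory data), plus packaging. Replacing
the synthetic blue colorant with phycocyanin at a dosage of 0.28 CU per kg
of product adds ``dosage * unit_mass * net_per_cu`` to the footprint —
negative when the colorant's net per-CU balance is a credit.

Corporate level: given an averaged Scope 1+2+3 footprint, the table of
reduction goals scales linearly: tonnes to cut, bags of recoloured product
needed, and color units of phycocyanin required. The per-bag reduction
(5.349 kg CO2-eq/bag) and the kg-per-CU conversion used for the last
column are back-solved reconstructions from the published table, not
printed values; users supply their own where available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "RecipeEntry",
    "ProductRecipe",
    "SubstitutionSpec",
    "CorporateProfile",
    "product_footprint",
    "substitute_colorant",
    "corporate_reduction_table",
]


@dataclass(frozen=True)
class RecipeEntry:
    """One recipe row: ingredient mass per product unit and its factor."""

    ingredient: str
    mass_kg: float
    emission_factor: float | None = None  # kg CO2-eq per kg; None = missing
    phase: str = "raw"  # raw | packaging

    def __post_init__(self) -> None:
        if self.mass_kg < 0:
            raise ValueError(f"{self.ingredient!r}: mass must be >= 0")
        if self.phase not in ("raw", "packaging"):
            raise ValueError(f"{self.ingredient!r}: phase must be 'raw' or 'packaging'")


@dataclass(frozen=True)
class ProductRecipe:
    entries: tuple[RecipeEntry, ...]
    production_overhead_fraction: float = 0.30
    unit_mass_kg: float = 0.100

    def __post_init__(self) -> None:
        if not 0 <= self.production_overhead_fraction <= 1:
            raise ValueError("production_overhead_fraction must be in [0, 1]")
        if self.unit_mass_kg <= 0:
            raise ValueError("unit_mass_kg must be positive")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple], factors: dict[str, float],
                  **kwargs) -> "ProductRecipe":
        """Build from (ingredient, mass_kg, phase, comment) rows + factor map."""
        entries = tuple(
            RecipeEntry(name, mass, factors.get(name), phase)
            for name, mass, phase, *_ in rows
        )
        return cls(entries, **kwargs)


def product_footprint(r: ProductRecipe) -> float:
    """Cradle-to-gate kg CO2-eq per product unit.

    ``raw * (1 + overhead) + packaging``. A missing emission factor is a
    hard error naming the ingredient — never an implicit zero.
    """
    missing = [e.ingredient for e in r.entries if e.emission_factor is None]
    if missing:
        raise ValueError(f"missing emission factors for ingredients: {missing}")
    raw = sum(e.mass_kg * e.emission_factor for e in r.entries if e.phase == "raw")
    packaging = sum(e.mass_kg * e.emission_factor for e in r.entries if e.phase == "packaging")
    return raw * (1.0 + r.production_overhead_fraction) + packaging


@dataclass(frozen=True)
class SubstitutionSpec:
    """Colorant substitution: dosage and the colorant's net per-CU balance.

    ``net_per_cu_kg`` should be the conservative, margin-applied net value
    (negative = credit). ``replaced_share_kg`` is the footprint share of
    the colorant being removed; it defaults to zero because the proxy
    colorant mass in the published recipe is negligible (0.0001 kg).
    """

    dosage_cu_per_kg: float = 0.28
    net_per_cu_kg: float = -1118.25
    replaced_colorant: str = "Spirulina, dried"
    replaced_share_kg: float = 0.0

    def __post_init__(self) -> None:
        if self.dosage_cu_per_kg < 0:
            raise ValueError("dosage must be >= 0")


def substitute_colorant(base_fp_kg: float, s: SubstitutionSpec,
                        unit_mass_kg: float = 0.100) -> float:
    """Footprint per product unit after swapping in the phycocyanin blue.

    ``base_fp - replaced_share + dosage * unit_mass * net_per_cu``.
    """
    if unit_mass_kg < 0:
        raise ValueError("unit_mass_kg must be >= 0")
    return (base_fp_kg - s.replaced_share_kg
            + s.dosage_cu_per_kg * unit_mass_kg * s.net_per_cu_kg)


def _default_goals() -> tuple[float, ...]:
    return (0.05, 0.10, 0.20, 0.50)


@dataclass(frozen=True)
class CorporateProfile:
    """Averaged corporate Scope 1+2+3 footprint and scaling conversions.

    ``total_scope123_t`` defaults to 26,374,480 t CO2-eq (an average over
    four major food/ingredient producers' ESG reports, back-computed from
    the published 5%-goal row of "~26.4 million"). ``per_bag_delta_kg``
    and ``kg_co2_per_cu`` are reconstructed conversion factors.
    """

    total_scope123_t: float = 26_374_480.0
    reduction_goals: tuple[float, ...] = field(default_factory=_default_goals)
    per_bag_delta_kg: float = 5.349
    kg_co2_per_cu: float = 9551.6

    def __post_init__(self) -> None:
        if self.total_scope123_t <= 0:
            raise ValueError("total_scope123_t must be positive")
        if self.per_bag_delta_kg <= 0:
            raise ValueError("per_bag_delta_kg must be positive")
        if self.kg_co2_per_cu <= 0:
            raise ValueError("kg_co2_per_cu must be positive")
        for g in self.reduction_goals:
            if not 0 < g <= 1:
                raise ValueError(f"reduction goal {g} outside (0, 1]")


def corporate_reduction_table(c: CorporateProfile = CorporateProfile()) -> pd.DataFrame:
    """Linear scaling of reduction goals to tonnes, bags and color units.

    Columns: ``goal_pct, reduction_t, bags, phycocyanin_cu``. Every column
    is proportional to the goal, so row ratios are constant by
    construction.
    """
    rows = []
    for goal in c.reduction_goals:
        reduction_t = goal * c.total_scope123_t
        rows.append(
            {
                "goal_pct": goal * 100.0,
                "reduction_t": reduction_t,
                "bags": reduction_t * 1000.0 / c.per_bag_delta_kg,
                "phycocyanin_cu": reduction_t * 1000.0 / c.kg_co2_per_cu,
            }
        )
    return pd.DataFrame(rows, columns=["goal_pct", "reduction_t", "bags", "phycocyanin_cu"])
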