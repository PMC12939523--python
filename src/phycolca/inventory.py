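"""Life cycle inventory data model and linear characterization engine.

An inventory is a set of per-functional-unit flows (materials, energy,
transport services, elementary exchanges). Characterization is the linear
map ``impact[category] = sum(amount_SI * direction_sign * factor)`` over
all flows that have a characterization factor for that category.

Sign convention: amounts are always non-negative; whether a flow is an
emission/input (+1) or a removal/uptake (-1) is carried exclusively by
``direction_sign``. Removals (CO2 biofixation during cultivation, soil
organic carbon sequestration) therefore enter category totals negatively
while the inventory table keeps its published positive amounts.

Units are converted to SI base units before applying factors (t -> kg
x1000, g -> kg x0.001); characterization factors are interpreted per SI
base unit of the flow (per kg, per MJ, per t·km, ...).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "InventoryEntry",
    "InventoryTable",
    "CharacterizationFactorTable",
    "ImpactResult",
    "read_inventory",
    "read_factors",
    "characterize",
    "stage_totals",
    "combine_stage_intensities",
]

#: Controlled unit vocabulary -> multiplier to the SI base unit.
UNIT_TO_SI: dict[str, float] = {
    "kg": 1.0,
    "t": 1000.0,
    "g": 0.001,
    "MJ": 1.0,
    "t·km": 1.0,
    "m2·a": 1.0,
    "L": 1.0,
    "item": 1.0,
}

#: Accepted spelling variants for awkward-to-type units.
_UNIT_ALIASES: dict[str, str] = {
    "t*km": "t·km",
    "tkm": "t·km",
    "t km": "t·km",
    "m2*a": "m2·a",
    "m2a": "m2·a",
    "m^2·a": "m2·a",
}

CATEGORIES = ("climate_GWP100", "water_AWARE", "land_quality")

COMPARTMENTS = ("technosphere", "elementary")


def _canonical_unit(unit: str) -> str:
    unit = unit.strip()
    return _UNIT_ALIASES.get(unit, unit)


@dataclass(frozen=True)
class InventoryEntry:
    """One inventory row: a flow amount per functional unit."""

    flow_name: str
    amount: float
    unit: str
    compartment: str
    direction_sign: int = 1
    stage: str = ""
    data_source: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _canonical_unit(self.unit))
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValueError(
                f"flow {self.flow_name!r}: amount must be finite and non-negative "
                f"(got {self.amount!r}); encode removals via direction_sign=-1"
            )
        if self.unit not in UNIT_TO_SI:
            raise ValueError(
                f"flow {self.flow_name!r}: unknown unit {self.unit!r}; "
                f"allowed: {sorted(UNIT_TO_SI)}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"flow {self.flow_name!r}: compartment must be one of {COMPARTMENTS}"
            )
        if self.direction_sign not in (1, -1):
            raise ValueError(f"flow {self.flow_name!r}: direction_sign must be +1 or -1")

    @property
    def amount_si(self) -> float:
        """Amount converted to the SI base unit of this flow."""
        return self.amount * UNIT_TO_SI[self.unit]


@dataclass
class InventoryTable:
    """An ordered collection of :class:`InventoryEntry`."""

    entries: list[InventoryEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def scaled(self, k: float) -> "InventoryTable":
        """Return a copy with every amount multiplied by ``k >= 0``."""
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return InventoryTable(
            [
                InventoryEntry(
                    e.flow_name, e.amount * k, e.unit, e.compartment,
                    e.direction_sign, e.stage, e.data_source, e.comment,
                )
                for e in self.entries
            ]
        )

    def __add__(self, other: "InventoryTable") -> "InventoryTable":
        return InventoryTable(list(self.entries) + list(other.entries))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "flow_name": e.flow_name,
                    "amount": e.amount,
                    "unit": e.unit,
                    "compartment": e.compartment,
                    "direction_sign": e.direction_sign,
                    "stage": e.stage,
                    "data_source": e.data_source,
                    "comment": e.comment,
                }
                for e in self.entries
            ],
            columns=[
                "flow_name", "amount", "unit", "compartment",
                "direction_sign", "stage", "data_source", "comment",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class CharacterizationFactorTable:
    """(flow_name, category) -> characterization factor.

    A missing pair is an explicit lookup error, never an implicit zero.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None,
                 units: Mapping[tuple[str, str], str] | None = None):
        self._factors: dict[tuple[str, str], float] = dict(entries or {})
        self._units: dict[tuple[str, str], str] = dict(units or {})
        for (flow, cat), f in self._factors.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown impact category {cat!r} for flow {flow!r}")
            if not math.isfinite(f):
                raise ValueError(f"non-finite factor for ({flow!r}, {cat!r})")

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._factors

    def factor(self, flow_name: str, category: str) -> float:
        try:
            return self._factors[(flow_name, category)]
        except KeyError:
            raise KeyError(
                f"no characterization factor for flow {flow_name!r} in "
                f"category {category!r} (missing pairs are never treated as zero)"
            ) from None

    def categories(self) -> list[str]:
        return sorted({cat for _, cat in self._factors})

    @classmethod
    def unit_co2(cls) -> "CharacterizationFactorTable":
        """Minimal GWP100 table: elementary CO2 counts 1:1 as CO2-eq."""
        return cls({("CO_2", "climate_GWP100"): 1.0},
                   {("CO_2", "climate_GWP100"): "kg CO2-eq/kg"})


@dataclass
class ImpactResult:
    """Per-category impact totals with optional per-stage breakdown."""

    totals: dict[str, float]
    breakdown: dict[str, dict[str, float]] = field(default_factory=dict)
    not_characterized: list[str] = field(default_factory=list)

    @property
    def climate(self) -> float:
        return self.totals["climate_GWP100"]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema": "phycolca.impact_result/1",
            "totals_kg_or_pt_or_m3": self.totals,
            "per_stage_breakdown": self.breakdown,
            "not_characterized": self.not_characterized,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


_REQUIRED_COLUMNS = ("flow_name", "amount", "unit", "compartment", "direction_sign")


def read_inventory(path: str | Path) -> InventoryTable:
    """Read an inventory CSV into an :class:`InventoryTable`.

    Expected columns: ``flow_name,amount,unit,compartment,direction_sign``
    plus optional ``stage,data_source,comment``. UTF-8, "." decimal
    separator. Rows with unknown units or negative amounts raise a
    ``ValueError`` that names the offending row.
    """
    df = pd.read_csv(path, dtype={"flow_name": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                InventoryEntry(
                    flow_name=str(row["flow_name"]),
                    amount=float(row["amount"]),
                    unit=str(row["unit"]),
                    compartment=str(row["compartment"]),
                    direction_sign=int(row["direction_sign"]),
                    stage=str(row.get("stage", "") or ""),
                    data_source=str(row.get("data_source", "") or ""),
                    comment=str(row.get("comment", "") or ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
    return InventoryTable(entries)


def read_factors(path: str | Path) -> CharacterizationFactorTable:
    """Read a factor CSV with columns ``flow_name,category,factor,factor_unit``."""
    df = pd.read_csv(path)
    for c in ("flow_name", "category", "factor"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    factors, units = {}, {}
    for _, row in df.iterrows():
        key = (str(row["flow_name"]), str(row["category"]))
        factors[key] = float(row["factor"])
        units[key] = str(row.get("factor_unit", "") or "")
    return CharacterizationFactorTable(factors, units)


def characterize(
    inv: InventoryTable,
    cf: CharacterizationFactorTable,
    categories: Iterable[str] = ("climate_GWP100",),
    ignore: Iterable[str] = (),
) -> ImpactResult:
    """Linearly characterize an inventory into per-category impact totals.

    Every *elementary* flow must either have a factor for each requested
    category or be listed in ``ignore``; otherwise a ``ValueError`` listing
    the unmatched flows is raised. Technosphere flows without a factor are
    recorded in ``not_characterized`` (background data the user chose not
    to model per-flow) rather than silently dropped.
    """
    categories = tuple(categories)
    ignore = set(ignore)
    totals = {cat: 0.0 for cat in categories}
    unmatched_elementary: list[str] = []
    not_characterized: list[str] = []
    for e in inv:
        for cat in categories:
            if (e.flow_name, cat) in cf:
                totals[cat] += e.amount_si * e.direction_sign * cf.factor(e.flow_name, cat)
            elif e.compartment == "elementary":
                if e.flow_name not in ignore:
                    unmatched_elementary.append(f"{e.flow_name} ({cat})")
            else:
                not_characterized.append(f"{e.flow_name} ({cat})")
    if unmatched_elementary:
        raise ValueError(
            "elementary flows without characterization factors and not in the "
            f"ignore set: {sorted(set(unmatched_elementary))}"
        )
    return ImpactResult(totals=totals, not_characterized=sorted(set(not_characterized)))


def stage_totals(
    inv: InventoryTable,
    cf: CharacterizationFactorTable,
    stage_labels: Mapping[str, str] | None = None,
    categories: Iterable[str] = ("climate_GWP100",),
    ignore: Iterable[str] = (),
) -> ImpactResult:
    """Characterize with a per-stage breakdown.

    The stage of each entry is its ``stage`` field, overridden by
    ``stage_labels`` (flow_name -> stage) when given. Every entry must map
    to exactly one non-empty stage. The breakdown sums to the total per
    category by construction.
    """
    categories = tuple(categories)
    by_stage: dict[str, InventoryTable] = {}
    unmapped = []
    for e in inv:
        stage = (stage_labels or {}).get(e.flow_name, e.stage)
        if not stage:
            unmapped.append(e.flow_name)
            continue
        by_stage.setdefault(stage, InventoryTable()).entries.append(e)
    if unmapped:
        raise ValueError(f"flows not mapped to any stage: {sorted(set(unmapped))}")
    breakdown: dict[str, dict[str, float]] = {}
    totals = {cat: 0.0 for cat in categories}
    not_characterized: list[str] = []
    for stage, sub in sorted(by_stage.items()):
        res = characterize(sub, cf, categories, ignore)
        breakdown[stage] = res.totals
        not_characterized.extend(res.not_characterized)
        for cat in categories:
            totals[cat] += res.totals[cat]
    return ImpactResult(totals=totals, breakdown=breakdown,
                        not_characterized=sorted(set(not_characterized)))


def combine_stage_intensities(intensities: Mapping[str, float],
                              signs: Mapping[str, int] | None = None) -> ImpactResult:
    """Aggregate pre-characterized stage climate intensities (kg CO2-eq/CU).

    Used when per-flow background factors are unavailable and stages are
    supplied as already-characterized totals; ``signs`` marks removal
    stages with -1.
    """
    signs = dict(signs or {})
    breakdown = {}
    total = 0.0
    for stage, value in intensities.items():
        signed = value * signs.get(stage, 1)
        breakdown[stage] = {"climate_GWP100": signed}
        total += signed
    return ImpactResult(totals={"climate_GWP100": total}, breakdown=breakdown)
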