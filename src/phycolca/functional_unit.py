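"""Color-unit arithmetic and the product/waste mass balance.

The functional unit of the analysis is one color unit (CU) of phycocyanin
extract, the industrial strength metric for blue Spirulina colorant:

    CU/kg = A618 * 10 * DF / (g * 100)

where A618 is the absorbance of a buffered solution at 618 nm, DF the
dilution factor and g the sample mass in grams. One CU corresponds to
approximately 7.12 g of phycocyanin (an extract strength of roughly
140 CU/kg). The pigment is extracted at a yield of 3.22% of dry biomass,
and a further 15.8% of the dry biomass leaves as the water-soluble waste
fraction that is valorised as a soil biostimulant — so every CU of pigment
drags a fixed mass of creditable waste along with it.

Note the published constants 7.12 g/CU and 140 CU/kg are mutually
inconsistent by ~0.3% (1000/140 = 7.143): 7.12 g/CU is treated as the
canonical value; 140 CU/kg is display metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ColorValueInputs",
    "MassBalanceParams",
    "MassBalanceResult",
    "color_value",
    "pigment_mass_per_cu",
    "mass_balance_per_cu",
    "PHYCOCYANIN_G_PER_CU",
    "NOMINAL_STRENGTH_CU_PER_KG",
]

#: Canonical pigment mass per color unit (grams).
PHYCOCYANIN_G_PER_CU = 7.12
#: Nominal extract strength, display metadata only.
NOMINAL_STRENGTH_CU_PER_KG = 140.0


@dataclass(frozen=True)
class ColorValueInputs:
    """Spectrophotometric inputs of the color-value formula."""

    A618: float
    DF: float = 1.0
    sample_mass_g: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A618", "DF", "sample_mass_g"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.A618 < 0:
            raise ValueError("absorbance A618 must be non-negative")
        if self.DF < 1:
            raise ValueError("dilution factor DF must be >= 1")
        if self.sample_mass_g <= 0:
            raise ValueError("sample_mass_g must be positive")


def color_value(inputs: ColorValueInputs) -> float:
    """Color units per kg of extract from absorbance, dilution and mass."""
    return inputs.A618 * 10.0 * inputs.DF / (inputs.sample_mass_g * 100.0)


def pigment_mass_per_cu(strength: float | None = None) -> float:
    """Grams of phycocyanin per color unit.

    With ``strength`` (CU per kg of extract) given, returns 1000/strength.
    Without it, returns the canonical constant 7.12 g/CU.
    """
    if strength is None:
        return PHYCOCYANIN_G_PER_CU
    if strength <= 0:
        raise ValueError("strength must be positive (CU per kg)")
    return 1000.0 / strength


@dataclass(frozen=True)
class MassBalanceParams:
    """Pigment yield and waste fraction of the dry-biomass mass balance.

    ``y_pc``: pigment extraction yield as a fraction of dry biomass
    (default 3.22%). ``f_w``: soluble waste fraction of dry biomass
    (default 15.8%), the biostimulant stream.
    """

    m_pc_per_cu: float = PHYCOCYANIN_G_PER_CU
    y_pc: float = 0.0322
    f_w: float = 0.158
    strength: float = NOMINAL_STRENGTH_CU_PER_KG  # display metadata

    def __post_init__(self) -> None:
        if not 0 < self.y_pc <= 1:
            raise ValueError("pigment yield y_pc must be in (0, 1]")
        if not 0 <= self.f_w <= 1:
            raise ValueError("waste fraction f_w must be in [0, 1]")
        if self.y_pc + self.f_w > 1 + 1e-12:
            raise ValueError("y_pc + f_w cannot exceed 1")
        if self.m_pc_per_cu <= 0:
            raise ValueError("m_pc_per_cu must be positive")


@dataclass(frozen=True)
class MassBalanceResult:
    dry_biomass_g_per_cu: float
    waste_g_per_cu: float
    phycocyanin_g_per_cu: float


def mass_balance_per_cu(p: MassBalanceParams = MassBalanceParams()) -> MassBalanceResult:
    """Dry biomass and waste mass dragged along per color unit.

    dry = m_pc / y_pc; waste = f_w * dry. With defaults this is
    7.12/0.0322 ≈ 221.12 g dry biomass and ≈ 34.94 g waste per CU.
    """
    dry = p.m_pc_per_cu / p.y_pc
    return MassBalanceResult(
        dry_biomass_g_per_cu=dry,
        waste_g_per_cu=p.f_w * dry,
        phycocyanin_g_per_cu=p.m_pc_per_cu,
    )
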