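"""Soil-organic-carbon crediting of the biostimulant waste stream.

Field data indicate that 1 g (dry weight) of the amino-acid-rich waste
stream, applied annually as a biostimulant at 47.6 g/ha/yr, drives a soil
organic carbon gain of about 25.0 kg SOC per year. Crediting converts this
to CO2-equivalents with the molar ratio 44/12 and applies two conservative
deductions:

* a 50% *reversal buffer* (reserve): only half the removal is credited, to
  insure against future loss of the stored carbon;
* an additional 30% *uncertainty margin*, applied only in case-study mode
  to the net negative balance (not to gross emissions).

This module returns positive removal magnitudes; the sign flip to negative
climate values happens at the impact-result layer.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SequestrationParams",
    "soc_per_gram",
    "co2e_per_gram",
    "sequestration_per_cu",
    "apply_margin",
    "area_required",
    "CANONICAL_SEQUESTRATION_KG_PER_CU",
]

#: Published per-CU credited sequestration flow (kg CO2-eq), the inventory
#: table's canonical value; exposed as a cross-check constant.
CANONICAL_SEQUESTRATION_KG_PER_CU = 1602.48


@dataclass(frozen=True)
class SequestrationParams:
    """Crediting parameters.

    r_soc
        kg SOC sequestered per g biostimulant per year (default 25.0).
    c_to_co2
        molar mass ratio CO2/C, 44/12 exactly by default. (The published
        rounded rates 91.8 / 45.9 kg CO2-eq per g imply ~3.672; the exact
        molar ratio is kept and the <=0.15% gap tolerated.)
    reversal_buffer
        fraction retained after the reserve (default 0.5).
    uncertainty_margin
        additional case-study deduction on the net balance (default 0.30).
    application_rate
        g biostimulant per hectare per year (default 47.6).
    """

    r_soc: float = 25.0
    c_to_co2: float = 44.0 / 12.0
    reversal_buffer: float = 0.5
    uncertainty_margin: float = 0.30
    application_rate: float = 47.6

    def __post_init__(self) -> None:
        if self.r_soc < 0:
            raise ValueError("r_soc must be >= 0")
        if not 0 < self.reversal_buffer <= 1:
            raise ValueError("reversal_buffer must be in (0, 1]")
        if not 0 <= self.uncertainty_margin < 1:
            raise ValueError("uncertainty_margin must be in [0, 1)")
        if not 3.6 <= self.c_to_co2 <= 3.7:
            raise ValueError("c_to_co2 must be a CO2/C molar ratio in [3.6, 3.7]")
        if self.application_rate < 0:
            raise ValueError("application_rate must be >= 0")


def soc_per_gram(p: SequestrationParams = SequestrationParams(),
                 buffered: bool = True) -> float:
    """kg SOC credited per g biostimulant per year.

    Unbuffered this is the raw rate (default 25.0); with the 50% reversal
    buffer it is 12.50.
    """
    return p.r_soc * (p.reversal_buffer if buffered else 1.0)


def co2e_per_gram(p: SequestrationParams = SequestrationParams(),
                  buffered: bool = True) -> float:
    """kg CO2-eq credited per g biostimulant per year (44/12 conversion).

    Defaults: 91.67 unbuffered, 45.83 buffered (published rounded values
    91.8 and 45.9).
    """
    return soc_per_gram(p, buffered) * p.c_to_co2


def sequestration_per_cu(waste_g_per_cu: float,
                         p: SequestrationParams = SequestrationParams(),
                         buffered: bool = True) -> float:
    """kg CO2-eq credited per CU from its waste mass (positive magnitude)."""
    if waste_g_per_cu < 0:
        raise ValueError("waste_g_per_cu must be >= 0")
    return waste_g_per_cu * co2e_per_gram(p, buffered)


def apply_margin(value_kg: float,
                 p: SequestrationParams = SequestrationParams()) -> float:
    """Apply the case-study uncertainty margin to a net (negative) balance.

    Returns ``value_kg * (1 - uncertainty_margin)``; with the defaults a
    net credit of 1597.50 kg becomes 1118.25 kg (~1.12 t).
    """
    return value_kg * (1.0 - p.uncertainty_margin)


def area_required(waste_g: float,
                  p: SequestrationParams = SequestrationParams()) -> float:
    """Hectare-years of application needed to spread ``waste_g`` grams."""
    if p.application_rate <= 0:
        raise ValueError("application_rate must be positive")
    if waste_g < 0:
        raise ValueError("waste_g must be >= 0")
    return waste_g / p.application_rate
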