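"""Net per-CU carbon footprint, one-at-a-time sensitivity, and scenarios.

The net GWP100 balance per color unit is

    net = (cultivation + extraction) - sequestration_credit

with defaults 0.15 + 4.83 - 1602.48 = -1597.50 kg CO2-eq/CU: the credit
for the waste-stream biostimulant dwarfs the gross production emissions,
so the colorant is strongly carbon-negative.

OAT sensitivity perturbs one parameter by a signed fraction ``delta`` while
holding the rest fixed. The sequestration rate scales the credit term
directly. The remaining parameters (cultivation energy, cultivation yield,
transport) act through named GWP *contributions* — per-CU kg CO2-eq
magnitudes that are not published and are back-solved from the published
sensitivity table; they are reconstructions, configurable by the user.
``linear`` contributions scale with (1+delta); ``inverse`` contributions
(yield-type: per-CU burden falls as yield rises) scale with 1/(1+delta).

Percentage changes follow the published sign convention:
``(net - baseline) / |baseline| * 100`` — a more negative net prints as a
negative percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .functional_unit import MassBalanceParams, mass_balance_per_cu
from .soc import SequestrationParams, sequestration_per_cu

__all__ = [
    "OATContribution",
    "StageEmissionProfile",
    "SensitivitySpec",
    "ScenarioSpec",
    "net_gwp_per_cu",
    "oat_sensitivity",
    "run_scenario",
    "percent_reduction",
    "SCENARIO_IDS",
]


@dataclass(frozen=True)
class OATContribution:
    """A named per-CU GWP contribution used by the OAT engine.

    ``magnitude`` is kg CO2-eq per CU; ``mode`` is ``linear`` (scales with
    1+delta) or ``inverse`` (scales with 1/(1+delta)). ``reconstructed``
    flags defaults back-solved from the published sensitivity table rather
    than printed directly.
    """

    magnitude: float
    mode: str = "linear"
    reconstructed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "inverse"):
            raise ValueError("mode must be 'linear' or 'inverse'")
        if not math.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValueError("contribution magnitude must be finite and >= 0")

    def response(self, delta: float) -> float:
        """Change in net GWP (kg/CU) caused by perturbing this parameter."""
        if self.mode == "linear":
            return self.magnitude * delta
        return self.magnitude * (1.0 / (1.0 + delta) - 1.0)


def _default_contributions() -> dict[str, OATContribution]:
    # Back-solved from the published +/-20% response rows; reconstructions,
    # not printed data.
    return {
        "cultivation_energy": OATContribution(5.15, "linear"),
        "cultivation_yield": OATContribution(6.72, "inverse"),
        "transport": OATContribution(0.75, "linear"),
    }


@dataclass(frozen=True)
class StageEmissionProfile:
    """Per-CU stage climate intensities (kg CO2-eq per CU).

    ``cultivation_kg_per_kg_wet`` (4.19 kg CO2-eq per kg wet biomass) is
    carried as metadata; no wet-to-dry conversion reconciling it with the
    per-CU figure is published, so none is asserted.
    """

    cultivation_kg_per_cu: float = 0.15
    extraction_kg_per_cu: float = 4.83
    cultivation_kg_per_kg_wet: float = 4.19
    biofixation_kg_per_cu: float = 0.40179  # removal magnitude, metadata
    contributions: dict[str, OATContribution] = field(default_factory=_default_contributions)

    def __post_init__(self) -> None:
        for name in ("cultivation_kg_per_cu", "extraction_kg_per_cu",
                     "cultivation_kg_per_kg_wet", "biofixation_kg_per_cu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def gross_emissions_kg_per_cu(self) -> float:
        return self.cultivation_kg_per_cu + self.extraction_kg_per_cu


@dataclass(frozen=True)
class SensitivitySpec:
    """One OAT perturbation: parameter id and signed fractional delta."""

    parameter: str
    delta: float

    def __post_init__(self) -> None:
        if not abs(self.delta) < 1:
            raise ValueError("|delta| must be < 1")


SCENARIO_IDS = (
    "S1_conservative_seq",
    "S2_optimized_cultivation",
    "S3_ground_application",
    "S4_high_pc_content",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named alternative system configuration.

    Recognised override keys (all optional, with scenario-specific
    defaults): ``seq_scale`` (S1, default 0.5), ``energy_reduction``
    (S2, default 0.9), ``ground_application_delta_kg`` (S3, default
    -1.60, reconstructed), ``y_pc`` (S4, default 0.20).
    """

    id: str
    overrides: dict[str, float] = field(default_factory=dict)

    _KNOWN = {"seq_scale", "energy_reduction", "ground_application_delta_kg", "y_pc"}

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS and self.id != "identity":
            raise ValueError(f"unknown scenario id {self.id!r}; known: {SCENARIO_IDS}")
        unknown = set(self.overrides) - self._KNOWN
        if unknown:
            raise ValueError(f"unknown scenario overrides: {sorted(unknown)}")


def net_gwp_per_cu(stages: StageEmissionProfile, seq_kg_per_cu: float) -> float:
    """Net climate balance: gross stage emissions minus the credit (kg/CU)."""
    if not (math.isfinite(seq_kg_per_cu) and seq_kg_per_cu >= 0):
        raise ValueError("seq_kg_per_cu must be finite and >= 0 (a magnitude)")
    return stages.gross_emissions_kg_per_cu - seq_kg_per_cu


def oat_sensitivity(
    stages: StageEmissionProfile,
    seq_kg_per_cu: float,
    specs: Iterable[SensitivitySpec],
) -> pd.DataFrame:
    """One-at-a-time sensitivity table.

    Returns a DataFrame with columns ``parameter, delta, net_kg_per_cu,
    pct_change``. ``sequestration_rate`` scales the credit term; any other
    parameter must name a contribution of the profile.
    """
    baseline = net_gwp_per_cu(stages, seq_kg_per_cu)
    rows = []
    for spec in specs:
        if spec.parameter == "sequestration_rate":
            net = stages.gross_emissions_kg_per_cu - seq_kg_per_cu * (1.0 + spec.delta)
        elif spec.parameter in stages.contributions:
            net = baseline + stages.contributions[spec.parameter].response(spec.delta)
        else:
            raise ValueError(
                f"unknown OAT parameter {spec.parameter!r}; known: "
                f"{['sequestration_rate', *stages.contributions]}"
            )
        rows.append(
            {
                "parameter": spec.parameter,
                "delta": spec.delta,
                "net_kg_per_cu": net,
                "pct_change": (net - baseline) / abs(baseline) * 100.0,
            }
        )
    return pd.DataFrame(rows, columns=["parameter", "delta", "net_kg_per_cu", "pct_change"])


def run_scenario(
    spec: ScenarioSpec,
    stages: StageEmissionProfile = StageEmissionProfile(),
    mass: MassBalanceParams = MassBalanceParams(),
    seq: SequestrationParams = SequestrationParams(),
    credit_kg_per_cu: float | None = None,
) -> tuple[float, float]:
    """Evaluate a named scenario; returns ``(net_kg_per_cu, pct_change)``.

    * S1 scales the sequestration credit (default x0.5).
    * S2 removes a fraction of the cultivation-energy contribution
      (default 90%).
    * S3 swaps drone application for ground application via a configured
      net delta (default -1.60 kg/CU, reconstructed).
    * S4 raises the pigment yield (default to 20%); because *all* per-CU
      flows — emissions and credit alike — scale with the biomass needed
      per CU, the whole net balance scales by y_old/y_new.

    ``credit_kg_per_cu`` overrides the mass-balance-derived credit (e.g.
    with the inventory table's canonical credited flow).
    """
    if credit_kg_per_cu is not None:
        credit = credit_kg_per_cu
    else:
        credit = sequestration_per_cu(mass_balance_per_cu(mass).waste_g_per_cu, seq)
    baseline = net_gwp_per_cu(stages, credit)
    ov = spec.overrides
    if spec.id == "identity":
        net = baseline
    elif spec.id == "S1_conservative_seq":
        net = stages.gross_emissions_kg_per_cu - credit * ov.get("seq_scale", 0.5)
    elif spec.id == "S2_optimized_cultivation":
        reduction = ov.get("energy_reduction", 0.9)
        if not 0 <= reduction <= 1:
            raise ValueError("energy_reduction must be in [0, 1]")
        net = baseline - reduction * stages.contributions["cultivation_energy"].magnitude
    elif spec.id == "S3_ground_application":
        net = baseline + ov.get("ground_application_delta_kg", -1.60)
    elif spec.id == "S4_high_pc_content":
        y_new = ov.get("y_pc", 0.20)
        if not 0 < y_new <= 1:
            raise ValueError("y_pc override must be in (0, 1]")
        net = baseline * (mass.y_pc / y_new)
    else:  # pragma: no cover - guarded by ScenarioSpec validation
        raise ValueError(f"unknown scenario {spec.id!r}")
    return net, (net - baseline) / abs(baseline) * 100.0


def percent_reduction(a: float, b: float) -> float:
    """Reduction of |b| relative to |a|, in percent: (|a|-|b|)/|a|*100."""
    if a == 0:
        raise ValueError("reference value a must be non-zero")
    return (abs(a) - abs(b)) / abs(a) * 100.0
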