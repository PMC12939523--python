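"""Run configuration: load, validate, and materialise parameter objects.

Configuration is a nested YAML/JSON mapping whose blocks map one-to-one
onto the parameter dataclasses of the analysis modules. Every default is
the corresponding published study value (or a documented reconstruction
where no value was published). Unknown keys are hard errors — a typo must
never silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .case_study import CorporateProfile, SubstitutionSpec
from .footprint import OATContribution, StageEmissionProfile
from .functional_unit import MassBalanceParams
from .soc import SequestrationParams
from .synthetic import TrialGeneratorParams, default_config_dict

__all__ = ["RunConfig", "load_config"]


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"config block {name!r}: unknown keys {sorted(unknown)}")
    return cls(**block)


@dataclass(frozen=True)
class BootstrapConfig:
    confidence: float = 0.90
    resamples: int = 10_000
    method: str = "did"

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.resamples < 100:
            raise ValueError("resamples must be >= 100")
        if self.method not in ("did", "exp_only"):
            raise ValueError("method must be 'did' or 'exp_only'")


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of all module parameters for one pipeline run."""

    mass: MassBalanceParams = MassBalanceParams()
    sequestration: SequestrationParams = SequestrationParams()
    stages: StageEmissionProfile = StageEmissionProfile()
    trial: TrialGeneratorParams = TrialGeneratorParams()
    corporate: CorporateProfile = CorporateProfile()
    substitution: SubstitutionSpec = SubstitutionSpec()
    bootstrap: BootstrapConfig = BootstrapConfig()
    #: Credited removal per CU (kg CO2-eq) taken from the inventory table;
    #: None derives it from the mass balance x crediting rate instead.
    credit_kg_per_cu: float | None = 1602.48
    overhead_fraction: float = 0.30
    unit_mass_kg: float = 0.100
    report_format: str = "json"
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.report_format not in ("json", "csv"):
            raise ValueError("report_format must be 'json' or 'csv'")


_KNOWN_BLOCKS = {"functional_unit", "sequestration", "stages", "case_study",
                 "trial", "bootstrap", "rng", "report_format"}


def config_from_dict(doc: dict) -> RunConfig:
    unknown = set(doc) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    defaults = default_config_dict()
    provenance = {}

    def merged(block: str) -> dict:
        base = dict(defaults.get(block, {}))
        user = doc.get(block, {}) or {}
        for k in base:
            provenance[f"{block}.{k}"] = "user_config" if k in user else "paper_default"
        base.update(user)
        return base

    fu = merged("functional_unit")
    mass = _build(MassBalanceParams, fu, "functional_unit")

    seq = _build(SequestrationParams, merged("sequestration"), "sequestration")

    st = merged("stages")
    credit = st.pop("sequestration_credit_kg_per_cu")
    contrib_doc = st.pop("contributions")
    contributions = {
        name: OATContribution(spec["magnitude"], spec.get("mode", "linear"))
        for name, spec in contrib_doc.items()
    }
    stages = StageEmissionProfile(contributions=contributions, **st)

    cs = merged("case_study")
    corporate = CorporateProfile(
        total_scope123_t=cs["total_scope123_t"],
        reduction_goals=tuple(cs["reduction_goals"]),
        per_bag_delta_kg=cs["per_bag_delta_kg"],
        kg_co2_per_cu=cs["kg_co2_per_cu"],
    )
    substitution = SubstitutionSpec(dosage_cu_per_kg=cs["dosage_cu_per_kg"])

    trial = _build(TrialGeneratorParams, merged("trial"), "trial")
    bootstrap = _build(BootstrapConfig, merged("bootstrap"), "bootstrap")

    return RunConfig(
        mass=mass, sequestration=seq, stages=stages, trial=trial,
        corporate=corporate, substitution=substitution, bootstrap=bootstrap,
        credit_kg_per_cu=credit,
        overhead_fraction=cs["production_overhead_fraction"],
        unit_mass_kg=cs["unit_mass_kg"],
        report_format=doc.get("report_format", "json"),
        provenance=provenance,
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config file; with no path, return the full defaults."""
    if path is None:
        return config_from_dict({})
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(doc)
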