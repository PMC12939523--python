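"""Synthetic field-trial and fixture generation.

No raw soil-core data from the Ölfus trial are published, so this module
generates tables with the statistical structure the analysis assumes:

* two sites (EXP treated, CTRL untreated) sampled at baseline T0 (n=9
  EXP, n=6 CTRL) and one year later T1 (n=9 each), 60 cm cores;
* per-core SOC stock = lognormal(site-time mean, between-core CV)
  x multiplicative normal analytical noise (CV 3.44% by default);
* the treated site's T1 mean is baseline + annual effect (default
  1.6 tC/ha/yr), the control's is baseline + a null effect (default 0).

Between-core variation is modelled lognormal because stocks are positive
and right-skewed; the real sites' between-core variability is unpublished
and the default 12% CV is an assumption, prominently configurable. Cores
are destructive samples at fresh positions, so T0/T1 draws are independent
by default; a paired mode adds a shared per-position multiplier for method
testing.

All randomness flows through a seeded ``numpy.random.default_rng``
(PCG64): identical parameters and seed give byte-identical tables on any
platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tables

__all__ = [
    "TrialGeneratorParams",
    "simulate_trial",
    "simulate_replicates",
    "make_fixtures",
    "FIXTURE_FILES",
]


@dataclass(frozen=True)
class TrialGeneratorParams:
    """Generator settings mirroring the field-trial design.

    ``baseline_stock_mean`` is the T0 SOC stock to 60 cm (tC/ha); the
    default 30.5 back-solves from a 1.34 tC/ha/yr gain being a 4.4%
    relative annual increase. Effects are additive on the site mean.
    """

    baseline_stock_mean: float = 30.5
    between_core_cv: float = 0.12
    analytical_cv: float = 0.0344
    annual_effect_exp: float = 1.6
    annual_effect_ctrl: float = 0.0
    n_exp_t0: int = 9
    n_ctrl_t0: int = 6
    n_exp_t1: int = 9
    n_ctrl_t1: int = 9
    site_lat: float = 64.0717
    site_lon: float = -21.4831
    paired: bool = False

    def __post_init__(self) -> None:
        if self.baseline_stock_mean <= 0:
            raise ValueError("baseline_stock_mean must be positive")
        if self.between_core_cv < 0 or self.analytical_cv < 0:
            raise ValueError("CVs must be >= 0")
        for name in ("n_exp_t0", "n_ctrl_t0", "n_exp_t1", "n_ctrl_t1"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.baseline_stock_mean + self.annual_effect_exp <= 0:
            raise ValueError("EXP T1 mean must stay positive")
        if self.baseline_stock_mean + self.annual_effect_ctrl <= 0:
            raise ValueError("CTRL T1 mean must stay positive")


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float,
                       n: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _noise_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative normal measurement noise, floored to stay positive."""
    if cv == 0:
        return np.ones(n)
    return np.clip(1.0 + rng.normal(0.0, cv, size=n), 1e-9, None)


def simulate_trial(p: TrialGeneratorParams = TrialGeneratorParams(),
                   seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic soil-core table for the two-site trial.

    Returns a DataFrame with columns ``site, time, sample_id,
    soc_stock_tc_ha, lat, lon``. The seed is mandatory.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    # CTRL plot offset ~0.6 km east of EXP; cores jittered within the
    # ~350 m square that a 12.45 ha site spans.
    site_centers = {
        "EXP": (p.site_lat, p.site_lon),
        "CTRL": (p.site_lat, p.site_lon + 0.011),
    }
    strata = [
        ("EXP", "T0", p.n_exp_t0, p.baseline_stock_mean),
        ("CTRL", "T0", p.n_ctrl_t0, p.baseline_stock_mean),
        ("EXP", "T1", p.n_exp_t1, p.baseline_stock_mean + p.annual_effect_exp),
        ("CTRL", "T1", p.n_ctrl_t1, p.baseline_stock_mean + p.annual_effect_ctrl),
    ]
    paired_factors: dict[str, np.ndarray] = {}
    rows = []
    for site, time, n, mean in strata:
        if p.paired and site in paired_factors and n == len(paired_factors[site]):
            base = paired_factors[site] * mean
        else:
            draws = _lognormal_mean_cv(rng, mean, p.between_core_cv, n)
            if p.paired and site not in paired_factors:
                paired_factors[site] = draws / mean
            base = draws
        stocks = base * _noise_factor(rng, p.analytical_cv, n)
        lat0, lon0 = site_centers[site]
        lats = lat0 + rng.uniform(-0.0016, 0.0016, size=n)
        lons = lon0 + rng.uniform(-0.0036, 0.0036, size=n)
        for i in range(n):
            rows.append(
                {
                    "site": site,
                    "time": time,
                    "sample_id": f"{site}-{time}-{i + 1:02d}",
                    "soc_stock_tc_ha": float(stocks[i]),
                    "lat": float(lats[i]),
                    "lon": float(lons[i]),
                }
            )
    df = pd.DataFrame(rows, columns=["site", "time", "sample_id",
                                     "soc_stock_tc_ha", "lat", "lon"])
    assert (df["soc_stock_tc_ha"] > 0).all()
    return df


def simulate_replicates(mean: float = 30.5, cv: float = 0.0344, n: int = 10,
                        seed: int | None = None) -> np.ndarray:
    """Replicate measurements of one sample under multiplicative noise."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    return mean * _noise_factor(rng, cv, n)


FIXTURE_FILES = (
    "inventory_cu.csv",
    "stage_intensities.csv",
    "recipe_dragee.csv",
    "dragee_emission_factors.csv",
    "config.yaml",
)


def default_config_dict() -> dict:
    """Default run configuration; every value is a package default."""
    return {
        "functional_unit": {
            "strength": 140.0, "m_pc_per_cu": 7.12, "y_pc": 0.0322, "f_w": 0.158,
        },
        "sequestration": {
            "r_soc": 25.0, "c_to_co2": round(44.0 / 12.0, 10),
            "reversal_buffer": 0.5, "uncertainty_margin": 0.30,
            "application_rate": 47.6,
        },
        "stages": {
            "cultivation_kg_per_cu": 0.15, "extraction_kg_per_cu": 4.83,
            "cultivation_kg_per_kg_wet": 4.19, "biofixation_kg_per_cu": 0.40179,
            # credited removal per CU from the inventory table; set to null
            # to derive it from the mass balance and sequestration rate
            "sequestration_credit_kg_per_cu": 1602.48,
            "contributions": {
                "cultivation_energy": {"magnitude": 5.15, "mode": "linear"},
                "cultivation_yield": {"magnitude": 6.72, "mode": "inverse"},
                "transport": {"magnitude": 0.75, "mode": "linear"},
            },
        },
        "case_study": {
            "production_overhead_fraction": 0.30, "unit_mass_kg": 0.100,
            "dosage_cu_per_kg": 0.28, "total_scope123_t": 26374480.0,
            "per_bag_delta_kg": 5.349, "kg_co2_per_cu": 9551.6,
            "reduction_goals": [0.05, 0.10, 0.20, 0.50],
        },
        "trial": {
            "baseline_stock_mean": 30.5, "between_core_cv": 0.12,
            "analytical_cv": 0.0344, "annual_effect_exp": 1.6,
            "annual_effect_ctrl": 0.0,
            "n_exp_t0": 9, "n_ctrl_t0": 6, "n_exp_t1": 9, "n_ctrl_t1": 9,
        },
        "bootstrap": {"confidence": 0.90, "resamples": 10000, "method": "did"},
        "rng": {"algorithm": "PCG64"},
    }


def make_fixtures(outdir) -> list[Path]:
    """Write the shipped reference fixtures to ``outdir``.

    Emits the per-CU inventory table (26 rows), the stage climate
    intensities, the dragee recipe with its synthetic emission-factor set,
    and the default configuration. Content is fully deterministic: running
    twice yields identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    inv = pd.DataFrame(
        tables.CU_INVENTORY,
        columns=["flow_name", "amount", "unit", "compartment",
                 "direction_sign", "stage", "data_source", "comment"],
    )
    path = out / "inventory_cu.csv"
    inv.to_csv(path, index=False)
    written.append(path)

    stages = pd.DataFrame(tables.STAGE_INTENSITIES,
                          columns=["stage", "kg_co2e_per_cu", "direction_sign"])
    path = out / "stage_intensities.csv"
    stages.to_csv(path, index=False)
    written.append(path)

    recipe = pd.DataFrame(tables.DRAGEE_RECIPE,
                          columns=["ingredient", "mass_kg", "phase", "comment"])
    path = out / "recipe_dragee.csv"
    recipe.to_csv(path, index=False)
    written.append(path)

    factors = pd.DataFrame(
        sorted(tables.DRAGEE_EMISSION_FACTORS.items()),
        columns=["ingredient", "kg_co2e_per_kg"],
    )
    factors["provenance"] = "synthetic_illustrative"
    path = out / "dragee_emission_factors.csv"
    factors.to_csv(path, index=False)
    written.append(path)

    path = out / "config.yaml"
    path.write_text(yaml.safe_dump(default_config_dict(), sort_keys=True))
    written.append(path)
    return written
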