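"""Statistics for the two-site, two-timepoint soil-core SOC field trial.

The trial design: an experimental site (EXP, biostimulant applied) and a
control site (CTRL), each ~12.45 ha, sampled with 60 cm cores at baseline
(T0: n=9 EXP, n=6 CTRL) and about one year later (T1: n=9 each). Cores
are destructive, so T0 and T1 samples are independent. Per-core SOC stocks
are taken as already-computed tC/ha.

Provided analyses:

* tie-corrected Kruskal–Wallis rank test between groups of stocks;
* analytical coefficient of variation from replicate measurements of one
  sample (instrument precision);
* the annual SOC stock increase with a one-sided percentile-bootstrap
  lower confidence bound — either the simple EXP change (T1 - T0) or,
  by default, the difference-in-differences contrast against CTRL;
* the relative annual increase against a baseline stock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialResult",
    "AnnualChange",
    "read_samples",
    "validate_samples",
    "kruskal_wallis",
    "analytical_cv",
    "annual_increase_lower_bound",
    "relative_increase",
    "trial_result",
]

SAMPLE_COLUMNS = ("site", "time", "sample_id", "soc_stock_tc_ha", "lat", "lon")
SITES = ("EXP", "CTRL")
TIMES = ("T0", "T1")


def read_samples(path) -> pd.DataFrame:
    """Read a soil-core sample CSV (site,time,sample_id,soc_stock_tc_ha,lat,lon)."""
    df = pd.read_csv(path)
    validate_samples(df)
    return df


def validate_samples(df: pd.DataFrame) -> None:
    missing = [c for c in ("site", "time", "soc_stock_tc_ha") if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns {missing}")
    bad_site = set(df["site"]) - set(SITES)
    if bad_site:
        raise ValueError(f"unknown site labels {sorted(bad_site)}; expected {SITES}")
    bad_time = set(df["time"]) - set(TIMES)
    if bad_time:
        raise ValueError(f"unknown time labels {sorted(bad_time)}; expected {TIMES}")
    if (df["soc_stock_tc_ha"] <= 0).any():
        raise ValueError("soc_stock_tc_ha must be strictly positive")


def _stratum(df: pd.DataFrame, site: str, time: str) -> np.ndarray:
    vals = df.loc[(df["site"] == site) & (df["time"] == time),
                  "soc_stock_tc_ha"].to_numpy(float)
    if vals.size == 0:
        raise ValueError(f"missing stratum {site}/{time} in sample table")
    return vals


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p-value (k-1 df).

    Each group needs at least two observations. If all observations are
    identical across groups there is no rank variation: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def analytical_cv(replicates) -> float:
    """Coefficient of variation (%) of replicate measurements: sd/mean*100.

    Sample standard deviation (ddof=1). Quantifies analytical/instrument
    precision from repeated measurement of a single homogenised sample.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean of replicates is zero; CV undefined")
    return float(x.std(ddof=1) / abs(mean) * 100.0)


@dataclass(frozen=True)
class AnnualChange:
    """Annual SOC stock change estimate with a one-sided lower bound."""

    point_tc_ha_yr: float
    lower_bound_tc_ha_yr: float
    confidence: float
    method: str
    resamples: int


def annual_increase_lower_bound(
    samples: pd.DataFrame,
    confidence: float = 0.90,
    resamples: int = 10_000,
    seed: int | None = None,
    method: str = "did",
    years_between: float = 1.0,
) -> AnnualChange:
    """Annual SOC increase and its one-sided lower confidence bound.

    ``method='did'`` (default) uses the difference-in-differences contrast
    (EXP_T1 - EXP_T0) - (CTRL_T1 - CTRL_T0); ``method='exp_only'`` uses
    EXP_T1 - EXP_T0. The bound is a seeded one-sided percentile bootstrap
    over cores, resampling within each stratum; for a fixed seed it is
    bit-reproducible.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if method not in ("did", "exp_only"):
        raise ValueError("method must be 'did' or 'exp_only'")
    if years_between <= 0:
        raise ValueError("years_between must be positive")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    validate_samples(samples)

    strata = {"e0": _stratum(samples, "EXP", "T0"), "e1": _stratum(samples, "EXP", "T1")}
    if method == "did":
        strata["c0"] = _stratum(samples, "CTRL", "T0")
        strata["c1"] = _stratum(samples, "CTRL", "T1")

    def statistic(means: dict[str, np.ndarray | float]) -> np.ndarray | float:
        delta = means["e1"] - means["e0"]
        if method == "did":
            delta = delta - (means["c1"] - means["c0"])
        return delta / years_between

    point = float(statistic({k: v.mean() for k, v in strata.items()}))

    rng = np.random.default_rng(seed)
    boot_means = {}
    for key, vals in strata.items():
        idx = rng.integers(0, vals.size, size=(resamples, vals.size))
        boot_means[key] = vals[idx].mean(axis=1)
    boot = np.asarray(statistic(boot_means))
    lower = float(np.quantile(boot, 1.0 - confidence))
    return AnnualChange(point, lower, confidence, method, resamples)


def relative_increase(delta_tc_ha_yr: float, baseline_stock_tc_ha: float) -> float:
    """Annual change as a percentage of the baseline stock."""
    if baseline_stock_tc_ha <= 0:
        raise ValueError("baseline stock must be positive")
    return delta_tc_ha_yr / baseline_stock_tc_ha * 100.0


@dataclass(frozen=True)
class TrialResult:
    H_statistic: float
    p_value: float
    annual_delta_mean: float
    lower_bound: float
    confidence: float
    relative_increase_pct: float
    cv_pct: float | None = None


def trial_result(
    samples: pd.DataFrame,
    confidence: float = 0.90,
    resamples: int = 10_000,
    seed: int | None = None,
    method: str = "did",
    replicates=None,
) -> TrialResult:
    """Full trial summary: group test, change estimate, bound, relative gain.

    The Kruskal–Wallis test compares EXP stocks at T1 against T0 (the
    primary treated-site contrast); the lower bound uses ``method``.
    """
    e0, e1 = _stratum(samples, "EXP", "T0"), _stratum(samples, "EXP", "T1")
    h, p = kruskal_wallis(e0, e1)
    change = annual_increase_lower_bound(samples, confidence, resamples, seed, method)
    rel = relative_increase(change.point_tc_ha_yr, float(e0.mean()))
    cv = analytical_cv(replicates) if replicates is not None else None
    return TrialResult(h, p, change.point_tc_ha_yr, change.lower_bound_tc_ha_yr,
                       confidence, rel, cv)
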