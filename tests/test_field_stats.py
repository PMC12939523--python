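"""Field-trial statistics: rank test, CV, bootstrap bound, relative gain."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phycolca.field_stats import (analytical_cv, annual_increase_lower_bound,
                                  kruskal_wallis, relative_increase,
                                  trial_result)
from phycolca.synthetic import TrialGeneratorParams, simulate_trial


def kruskal_oracle(*groups):
    """Brute-force tie-corrected Kruskal-Wallis H via explicit mid-ranks."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n_total = pooled.size
    order = np.sort(pooled)
    # average rank for each value (mid-ranks for ties), 1-based
    ranks = {}
    i = 0
    while i < n_total:
        j = i
        while j < n_total and order[j] == order[i]:
            j += 1
        ranks[order[i]] = (i + 1 + j) / 2.0
        i = j
    h = 0.0
    for g in groups:
        r = sum(ranks[v] for v in np.asarray(g, float))
        h += r * r / len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n_total ** 3 - n_total)
    return h / correction


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        h, p = kruskal_wallis([5.0, 5.0, 5.0], [5.0, 5.0])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_match_rank_oracle(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(kruskal_oracle([1, 2, 3], [4, 5, 6]))
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(1 - sps.chi2.cdf(h, df=1))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_groups_with_ties_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 4)
        groups = [rng.integers(0, 5, size=rng.integers(2, 11)).astype(float)
                  for _ in range(k)]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            return  # degenerate all-identical draw covered elsewhere
        h, _ = kruskal_wallis(*groups)
        assert h == pytest.approx(kruskal_oracle(*groups), rel=1e-9)

    def test_small_group_is_hard_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_wallis([1.0], [2.0, 3.0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(10, 1, 9), rng.normal(11, 1, 9)
        h1, _ = kruskal_wallis(a, b)
        h2, _ = kruskal_wallis(np.exp(a / 5), np.exp(b / 5))
        assert h1 == pytest.approx(h2, rel=1e-12)


class TestAnalyticalCv:
    def test_constant_replicates(self):
        assert analytical_cv([7.0, 7.0, 7.0]) == 0.0

    def test_two_point_hand_value(self):
        # sd(ddof=1) = sqrt(2), mean = 11 -> 12.86%
        assert analytical_cv([10.0, 12.0]) == pytest.approx(
            np.sqrt(2.0) / 11.0 * 100.0)
        assert analytical_cv([10.0, 12.0]) == pytest.approx(12.86, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            analytical_cv([5.0])
        with pytest.raises(ValueError):
            analytical_cv([-1.0, 1.0])


def zero_effect_table():
    """T1 stocks exactly equal T0 stocks on both sites."""
    rng = np.random.default_rng(11)
    rows = []
    for site, n in (("EXP", 9), ("CTRL", 6)):
        vals = rng.normal(30, 1, n)
        for t in ("T0", "T1"):
            for i, v in enumerate(vals):
                rows.append({"site": site, "time": t, "sample_id": f"{site}{t}{i}",
                             "soc_stock_tc_ha": v, "lat": 64.07, "lon": -21.48})
    return pd.DataFrame(rows)


class TestLowerBound:
    def test_no_change_gives_zero_point_and_nonpositive_bound(self):
        df = zero_effect_table()
        res = annual_increase_lower_bound(df, seed=5, resamples=2000)
        assert res.point_tc_ha_yr == pytest.approx(0.0, abs=1e-12)
        assert res.lower_bound_tc_ha_yr <= 0.0
        assert res.lower_bound_tc_ha_yr <= res.point_tc_ha_yr

    def test_bit_reproducible_for_fixed_seed(self):
        df = simulate_trial(TrialGeneratorParams(), seed=4)
        a = annual_increase_lower_bound(df, seed=9, resamples=1000)
        b = annual_increase_lower_bound(df, seed=9, resamples=1000)
        assert a == b

    def test_converges_with_resamples(self):
        df = simulate_trial(TrialGeneratorParams(), seed=4)
        b1 = annual_increase_lower_bound(df, seed=1, resamples=20_000)
        b2 = annual_increase_lower_bound(df, seed=2, resamples=20_000)
        assert b1.lower_bound_tc_ha_yr == pytest.approx(
            b2.lower_bound_tc_ha_yr, abs=0.15)

    def test_exp_only_contrast_ignores_control(self):
        df = simulate_trial(TrialGeneratorParams(), seed=4)
        res = annual_increase_lower_bound(df, seed=9, method="exp_only",
                                          resamples=1000)
        e0 = df.query("site == 'EXP' and time == 'T0'")["soc_stock_tc_ha"].mean()
        e1 = df.query("site == 'EXP' and time == 'T1'")["soc_stock_tc_ha"].mean()
        assert res.point_tc_ha_yr == pytest.approx(e1 - e0)

    def test_missing_stratum_is_hard_error(self):
        df = simulate_trial(TrialGeneratorParams(), seed=4)
        with pytest.raises(ValueError, match="missing stratum"):
            annual_increase_lower_bound(df[df["site"] == "EXP"], seed=1,
                                        resamples=500)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            annual_increase_lower_bound(zero_effect_table())


class TestRelativeIncrease:
    @pytest.mark.parametrize("delta, base, expected", [
        (0.0, 30.0, 0.0),
        (1.2, 30.0, 4.0),
        (1.34, 30.45, 4.4),
    ])
    def test_values(self, delta, base, expected):
        assert relative_increase(delta, base) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_increase(1.0, 0.0)


def test_trial_result_bundles_consistent_statistics():
    df = simulate_trial(TrialGeneratorParams(), seed=21)
    res = trial_result(df, seed=3, resamples=2000, replicates=[30.0, 31.0, 29.5])
    assert 0.0 <= res.p_value <= 1.0
    assert res.lower_bound <= res.annual_delta_mean
    assert res.cv_pct == pytest.approx(analytical_cv([30.0, 31.0, 29.5]))
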