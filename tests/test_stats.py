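from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peeprd.stats_analysis import (
    ansari_bradley,
    dunn_sidak_posthoc,
    fit_regression,
    kruskal_wallis,
    run_q_battery,
    wilcoxon_paired,
)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kw_identical_groups_is_null():
    h, p = kruskal_wallis([np.ones(4), np.ones(4), np.ones(4)])
    assert h == 0.0 and p == 1.0


def test_kw_matches_rank_formula_oracle():
    """Groups (1,2,3),(4,5,6),(7,8,9): ranks are 1..9, mean ranks 2,5,8,
    H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2 = 12/90 * 3*(9+0+9) = 7.2."""
    h, p = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6]),
                           np.array([7, 8, 9])])
    assert h == pytest.approx(7.2)
    assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)))


def test_kw_tie_correction_matches_hand_formula():
    groups = [np.array([1.0, 1.0, 2.0]), np.array([2.0, 3.0, 3.0])]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    rbar = (n + 1) / 2
    h_raw = 12 / (n * (n + 1)) * sum(
        g.size * (ranks[i * 3:(i + 1) * 3].mean() - rbar) ** 2
        for i, g in enumerate(groups))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    h, _ = kruskal_wallis(groups)
    assert h == pytest.approx(h_raw / correction)


def test_kw_preconditions():
    with pytest.raises(ValueError):
        kruskal_wallis([np.array([1.0])])
    with pytest.raises(ValueError):
        kruskal_wallis([np.array([1.0]), np.array([2.0])])


# ---------------------------------------------------------------------------
# Dunn-Sidak post hoc
# ---------------------------------------------------------------------------

def test_sidak_identity_for_single_pair():
    rng = np.random.default_rng(1)
    groups = [rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
    gc = dunn_sidak_posthoc(groups, pairs=[(0, 1)])
    # m = 1: adjusted p equals the raw Dunn p
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    z = (ranks[:10].mean() - ranks[10:].mean()) / np.sqrt(
        (20 * 21 / 12) * (1 / 10 + 1 / 10))
    p_raw = 2 * sps.norm.sf(abs(z))
    assert gc.pairwise["p_adj"].iloc[0] == pytest.approx(p_raw)


def test_identical_groups_adjusted_p_is_one():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    gc = dunn_sidak_posthoc([g, g.copy()])
    assert gc.pairwise["p_adj"].iloc[0] == pytest.approx(1.0)
    assert not gc.pairwise["significant"].iloc[0]


def test_sidak_adjustment_is_monotone():
    rng = np.random.default_rng(2)
    groups = [rng.normal(i * 0.5, 1, 12) for i in range(4)]
    gc = dunn_sidak_posthoc(groups)
    m = len(gc.pairwise)
    assert m == 6
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    pos = 0
    mean_ranks = []
    for g in groups:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        pos += g.size
    for _, row in gc.pairwise.iterrows():
        i, j = int(row["x"]), int(row["y"])
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(
            (48 * 49 / 12) * (2 / 12))
        p_raw = 2 * sps.norm.sf(abs(z))
        assert row["p_adj"] >= p_raw - 1e-12        # adjustment never lowers p
        assert row["p_adj"] == pytest.approx(1 - (1 - p_raw) ** m)


def test_separated_groups_flag_far_pair():
    rng = np.random.default_rng(3)
    groups = [rng.normal(0, 0.5, 20), rng.normal(1, 0.5, 20), rng.normal(4, 0.5, 20)]
    gc = dunn_sidak_posthoc(groups, labels=["a", "b", "c"])
    table = gc.pairwise.set_index(["x", "y"])
    assert table.loc[("a", "c"), "significant"]
    assert table.loc[("a", "c"), "p_adj"] < table.loc[("a", "b"), "p_adj"]
    # CI of the raw mean difference brackets it
    row = table.loc[("a", "c")]
    assert row["ci_low"] < row["mean_diff"] < row["ci_high"]


# ---------------------------------------------------------------------------
# Ansari-Bradley
# ---------------------------------------------------------------------------

def test_ab_same_sample_twice_is_null():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t = ansari_bradley(x, x.copy())
    assert t.p == 1.0
    assert not t.reject


def test_ab_exact_matches_brute_force_enumeration():
    x = np.array([1.1, 3.2, 5.0, 9.3])
    y = np.array([4.1, 4.9, 5.5, 6.2])
    t = ansari_bradley(x, y, "two-sided", center=False)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    scores = np.empty(8)
    scores[order] = [min(i + 1, 8 - i) for i in range(8)]
    obs = scores[:4].sum()
    dist = np.array([scores[list(c)].sum() for c in combinations(range(8), 4)])
    p_le = np.mean(dist <= obs)
    p_ge = np.mean(dist >= obs)
    assert t.statistic == pytest.approx(obs)
    assert t.method == "exact"
    assert t.p == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))
    t_g = ansari_bradley(x, y, "greater", center=False)
    assert t_g.p == pytest.approx(p_le)
    t_l = ansari_bradley(x, y, "less", center=False)
    assert t_l.p == pytest.approx(p_ge)


def test_ab_agrees_with_scipy_reference_exact():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1.5, 8)
    y = rng.normal(0, 1.0, 9)   # pooled n = 17: both implementations exact
    mine = ansari_bradley(x, y, "two-sided", center=False)
    ref = sps.ansari(x, y)
    assert mine.method == "exact"
    assert mine.statistic == pytest.approx(ref.statistic)
    assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_ab_normal_approximation_tracks_exact_reference():
    rng = np.random.default_rng(17)
    x = rng.normal(0, 1.4, 15)
    y = rng.normal(0, 1.0, 16)  # pooled n = 31: mine approximates, scipy exact
    mine = ansari_bradley(x, y, "two-sided", center=False)
    ref = sps.ansari(x, y)
    assert mine.method == "normal"
    assert mine.statistic == pytest.approx(ref.statistic)
    assert mine.p == pytest.approx(ref.pvalue, rel=0.2)


def test_ab_one_tailed_detects_wider_sample():
    rng = np.random.default_rng(8)
    x = rng.normal(0, 4, 25)
    y = rng.normal(0, 1, 25)
    assert ansari_bradley(x, y, "greater").reject
    assert not ansari_bradley(y, x, "greater").reject


def test_ab_degenerate_pooled_sample():
    t = ansari_bradley(np.ones(5), np.ones(5), center=False)
    assert t.p == 1.0


def test_ab_null_calibration_exact_path():
    """Exchangeable null, exact enumeration: the one-sided test at n=10 vs 9
    has attained size exactly 0.05; the empirical rate must sit near it."""
    rng = np.random.default_rng(42)
    rej = sum(
        ansari_bradley(rng.normal(0, 1, 10), rng.normal(0, 1, 9),
                       "greater", center=False).reject
        for _ in range(400)
    )
    assert 0.03 <= rej / 400 <= 0.07


def test_ab_centering_is_conservative_not_anticonservative():
    rng = np.random.default_rng(43)
    rej = sum(
        ansari_bradley(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                       "two-sided", center=True).reject
        for _ in range(400)
    )
    assert rej / 400 <= 0.07


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_matches_sign_flip_enumeration():
    """n = 10 paired differences, no ties: exact p equals the enumeration
    over all 2^n sign assignments of the ranked |d|."""
    rng = np.random.default_rng(5)
    x = rng.normal(0.4, 1, 10)
    y = rng.normal(0.0, 1, 10)
    w, p = wilcoxon_paired(x, y)
    d = x - y
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    stats = np.array([
        ranks[[(m >> k) & 1 == 1 for k in range(n)]].sum()
        for m in range(2**n)
    ])
    p_exact = min(1.0, 2 * min(np.mean(stats <= min(w_obs, ranks.sum() - w_obs)),
                               np.mean(stats >= max(w_obs, ranks.sum() - w_obs))))
    assert p == pytest.approx(p_exact, rel=1e-9)


def test_wilcoxon_no_difference():
    x = np.arange(5.0)
    assert wilcoxon_paired(x, x.copy()) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def test_exact_cubic_interpolation():
    x = np.arange(10.0)
    coef = np.array([0.01, -0.2, 1.4, 10.6])
    y = np.polyval(coef, x)
    fit = fit_regression(x, y, 3)
    assert fit.r2 == pytest.approx(1.0)
    np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-9, atol=1e-9)


def test_constant_response_has_zero_r2():
    fit = fit_regression(np.arange(10.0), np.full(10, 3.3), 1)
    assert fit.r2 == 0.0


def test_regression_matches_statsmodels_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(6)
    x = rng.uniform(0, 15, 40)
    y = 1.0 * x + 9.1 + rng.normal(0, 2, 40)
    fit = fit_regression(x, y, 1)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    assert fit.coefficients[0] == pytest.approx(res.params[1], rel=1e-9)
    assert fit.coefficients[1] == pytest.approx(res.params[0], rel=1e-9)
    assert fit.r2 == pytest.approx(res.rsquared, rel=1e-9)
    assert fit.p == pytest.approx(res.f_pvalue, rel=1e-6)


def test_regression_preconditions():
    with pytest.raises(ValueError):
        fit_regression(np.arange(3.0), np.arange(3.0), 2)
    with pytest.raises(ValueError):
        fit_regression(np.ones(10), np.arange(10.0), 1)


# ---------------------------------------------------------------------------
# Q battery
# ---------------------------------------------------------------------------

def test_battery_trends_on_synthetic_study(default_study):
    rep = default_study.report
    q1 = rep.sections["q1"]
    assert q1["rr_fit"].coefficients[0] < 0      # rate falls with PEEP
    assert q1["tv_fit"].coefficients[0] > 0      # tidal volume rises
    q3 = rep.sections["q3"]
    assert q3["kw_pooled"].p < 0.05
    assert "q5" in rep.sections
    assert rep.sections["q5"]["degree1"].coefficients[0] > 0
    t2 = rep.tables["q3_table2_up_vs_down"]
    assert set(t2.columns) >= {"ci_low", "mean_diff", "ci_high", "p_adj"}


def test_battery_null_behavior_with_constant_rd():
    """Constant R/D at every PEEP: Q3 and Q4 must not reject anywhere."""
    rows = []
    rng = np.random.default_rng(9)
    for peep in (0.0, 3.0, 6.0):
        for d in ("up", "down"):
            for i in range(8):
                rows.append({"peep": peep, "direction": d,
                             "rd_pct_eelv": 2.0})
    rd_df = pd.DataFrame(rows)
    breath_df = pd.DataFrame({
        "peep": np.repeat([0.0, 3.0, 6.0], 10),
        "rr_local": rng.normal(60, 5, 30),
        "tv": rng.normal(0.2, 0.02, 30),
        "ptp_max": rng.normal(15, 2, 30),
        "included": True,
    })
    rep = run_q_battery(breath_df, rd_df)
    assert rep.sections["q3"]["kw_pooled"].p == 1.0
    t3 = rep.tables["q4_table3_dispersion_pairs"]
    assert not t3["h"].any()


def test_battery_skips_missing_sections_gracefully():
    rep = run_q_battery(pd.DataFrame(columns=["peep", "rr_local", "tv",
                                              "ptp_max", "included"]),
                        pd.DataFrame())
    assert "q3" not in rep.sections
    assert "q5" not in rep.sections
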