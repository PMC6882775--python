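"""Nonparametric statistical battery for PEEP-ramp studies (Q1-Q5).

Five questions are asked of the per-breath and per-breath-R/D tables:

Q1  Does respiratory drive track PEEP?  Linear regressions of breathing
    rate and tidal volume on PEEP.
Q2  Do the aeration compartments shift with PEEP?  Wilcoxon signed-rank
    comparisons of end-expiratory compartment quantities between the PEEP
    extremes.
Q3  Is tidal recruitment/derecruitment (R/D) driven by PEEP?
    Kruskal-Wallis across PEEP levels (pooled over ramp directions and per
    limb) with Dunn-Sidak post hoc pairwise comparisons, including
    same-PEEP ascending-vs-descending couples.
Q4  Is R/D more *variable* at low PEEP?  Ansari-Bradley dispersion tests:
    one-tailed over all PEEP pairs (alternative: the lower PEEP is more
    dispersed) and two-tailed ascending-vs-descending at each PEEP.
Q5  Does maximal transpulmonary pressure depend on PEEP?  Polynomial
    regressions of degree 1-3.

The Ansari-Bradley test is implemented here (median-centered samples,
symmetric scores, exact enumeration of the permutation null for pooled
n <= 20 without ties, finite-population normal approximation otherwise);
Kruskal-Wallis and Wilcoxon delegate to scipy behind this module's surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "DispersionTest",
    "RegressionFit",
    "QBatteryReport",
    "kruskal_wallis",
    "dunn_sidak_posthoc",
    "ansari_bradley",
    "wilcoxon_paired",
    "fit_regression",
    "run_q_battery",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Omnibus rank test plus pairwise post hoc table.

    ``pairwise`` rows: x, y, ci_low, mean_diff, ci_high, p_adj, significant.
    Mean differences and their normal-approximation confidence intervals are
    on the raw scale; the significance flag follows the rank-based
    Dunn z-test with Sidak-adjusted p.
    """

    labels: list
    h: float
    p: float
    pairwise: pd.DataFrame


@dataclass
class DispersionTest:
    statistic: float   # Ansari-Bradley score sum of the first sample
    p: float
    tail: str          # "two-sided" | "greater" | "less" (dispersion of x vs y)
    reject: bool       # at the alpha the test was run with
    method: str        # "exact" | "normal"


@dataclass
class RegressionFit:
    degree: int
    coefficients: np.ndarray  # highest power first
    r2: float
    p: float                  # overall F-test


@dataclass
class QBatteryReport:
    """Q1-Q5 results: scalar summaries plus the Tables-1-to-4-shaped frames."""

    sections: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def summary(self) -> dict:
        def _clean(v):
            if isinstance(v, RegressionFit):
                return {"degree": v.degree, "coefficients": list(v.coefficients),
                        "r2": v.r2, "p": v.p}
            if isinstance(v, GroupComparison):
                return {"labels": list(v.labels), "H": v.h, "p": v.p}
            if isinstance(v, DispersionTest):
                return {"statistic": v.statistic, "p": v.p, "tail": v.tail,
                        "reject": v.reject, "method": v.method}
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return float(v)
            return v

        return {"sections": _clean(self.sections), "notes": list(self.notes)}


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = k-1)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_sidak_posthoc(
    groups: list[np.ndarray],
    labels: list | None = None,
    alpha: float = 0.05,
    pairs: list[tuple[int, int]] | None = None,
) -> GroupComparison:
    """Dunn rank post hoc with Sidak multiple-comparison correction.

    ``pairs`` restricts the comparisons (indices into ``groups``); by
    default all unordered pairs are tested.  The Sidak adjustment is
    ``p_adj = 1 - (1 - p_raw)^m`` with m the number of comparisons; the
    confidence intervals for the raw mean differences use pooled variance
    at the Sidak-adjusted simultaneous level.
    """
    groups = [np.asarray(g, float) for g in groups]
    if labels is None:
        labels = list(range(len(groups)))
    if len(groups) < 2:
        return GroupComparison(labels=labels, h=0.0, p=1.0,
                               pairwise=pd.DataFrame())
    h, p_omni = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1))
    rank_var = n_tot * (n_tot + 1) / 12.0 - tie_term
    mean_ranks, sizes, means, variances = [], [], [], []
    pos = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[pos : pos + g.size])))
        sizes.append(g.size)
        means.append(float(np.mean(g)))
        variances.append(float(np.var(g, ddof=1)) if g.size > 1 else 0.0)
        pos += g.size

    if pairs is None:
        pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    alpha_sidak = 1.0 - (1.0 - alpha) ** (1.0 / m) if m else alpha
    z_crit = sps.norm.ppf(1.0 - alpha_sidak / 2.0)
    rows = []
    for i, j in pairs:
        ni, nj = sizes[i], sizes[j]
        se_rank = np.sqrt(rank_var * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se_rank if se_rank > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, 1.0 - (1.0 - min(p_raw, 1.0)) ** m)
        diff = means[i] - means[j]
        dof = ni + nj - 2
        sp = np.sqrt(((ni - 1) * variances[i] + (nj - 1) * variances[j]) / dof) \
            if dof > 0 else 0.0
        half = z_crit * sp * np.sqrt(1.0 / ni + 1.0 / nj)
        rows.append({
            "x": labels[i], "y": labels[j],
            "ci_low": diff - half, "mean_diff": diff, "ci_high": diff + half,
            "p_adj": p_adj, "significant": p_adj < alpha,
        })
    return GroupComparison(labels=labels, h=h, p=p_omni,
                           pairwise=pd.DataFrame(rows))


def _ab_scores(pooled: np.ndarray) -> np.ndarray:
    """Symmetric Ansari-Bradley scores of the pooled sample (mid-scores on ties)."""
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    base = np.minimum(np.arange(1, n + 1), n + 1 - np.arange(1, n + 1)).astype(float)
    scores = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        scores[order[i : j + 1]] = base[i : j + 1].mean()
        i = j + 1
    return scores


def _ab_exact_pmf(scores: np.ndarray, nx: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the score sum over all C(N, nx) assignments (integer scores)."""
    s_int = scores.astype(int)
    smax = int(s_int.sum())
    # dp[k, s]: number of size-k subsets with score sum s
    dp = np.zeros((nx + 1, smax + 1))
    dp[0, 0] = 1.0
    for a in s_int:
        dp[1 : nx + 1, a:] += dp[0:nx, : smax + 1 - a]
    total = dp[nx].sum()
    support = np.arange(smax + 1)
    return support, dp[nx] / total


def ansari_bradley(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    alpha: float = 0.05,
    center: bool = True,
) -> DispersionTest:
    """Ansari-Bradley test for equality of dispersion of two samples.

    ``alternative="greater"`` tests whether ``x`` is *more* dispersed than
    ``y`` (small score sums of ``x`` are evidence for it), ``"less"`` the
    reverse.  Samples are centered on their own medians by default, so
    unequal locations do not masquerade as unequal scale.  The null
    distribution is enumerated exactly for pooled n <= 20 without ties,
    otherwise a finite-population normal approximation (tie-aware, with
    continuity correction in the untied case) is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if center:
        x = x - np.median(x)
        y = y - np.median(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return DispersionTest(statistic=float(x.size), p=1.0, tail=alternative,
                              reject=False, method="degenerate")
    scores = _ab_scores(pooled)
    an = float(scores[: x.size].sum())
    n = pooled.size
    has_ties = np.unique(pooled).size < n

    if n <= 20 and not has_ties:
        support, pmf = _ab_exact_pmf(scores, x.size)
        p_le = float(pmf[support <= an].sum())
        p_ge = float(pmf[support >= an].sum())
        method = "exact"
    else:
        mean_s = scores.mean()
        var_pop = np.mean((scores - mean_s) ** 2)
        mu = x.size * mean_s
        var = x.size * (n - x.size) / (n - 1.0) * var_pop
        sd = np.sqrt(var)
        cc = 0.0 if has_ties else 0.5
        p_le = float(sps.norm.cdf((an - mu + cc) / sd))
        p_ge = float(sps.norm.sf((an - mu - cc) / sd))
        method = "normal"
        if has_ties:
            logger.debug("ansari_bradley: ties present, normal approximation used")

    if alternative == "greater":       # x more dispersed -> AN small
        p = p_le
    elif alternative == "less":
        p = p_ge
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return DispersionTest(statistic=an, p=p, tail=alternative,
                          reject=p < alpha, method=method)


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (exact for small n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    res = sps.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def fit_regression(x: np.ndarray, y: np.ndarray, degree: int) -> RegressionFit:
    """Polynomial least squares with R^2 and the overall F-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n <= degree + 1:
        raise ValueError("need n > degree + 1 observations")
    if np.all(x == x[0]):
        raise ValueError("x values are all equal; regression undefined")
    X = np.vander(x, degree + 1)  # highest power first
    sv = np.linalg.svd(X / np.linalg.norm(X, axis=0), compute_uv=False)
    if sv[-1] < 1e-10:
        raise ValueError("rank-deficient polynomial design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    dof = n - degree - 1
    if ss_res <= 0:
        p = 0.0
    elif ss_tot <= ss_res:
        p = 1.0
    else:
        f = ((ss_tot - ss_res) / degree) / (ss_res / dof)
        p = float(sps.f.sf(f, degree, dof))
    return RegressionFit(degree=degree, coefficients=coef, r2=r2, p=p)


# ---------------------------------------------------------------------------
# the Q1-Q5 battery
# ---------------------------------------------------------------------------

def _groups_by(df: pd.DataFrame, value: str, keys: list[str]) -> tuple[list, list]:
    labels, groups = [], []
    for key, g in df.groupby(keys, sort=True):
        if isinstance(key, tuple) and len(key) == 1:
            key = key[0]
        vals = g[value].dropna().to_numpy()
        if vals.size == 0:
            logger.info("run_q_battery: empty group %s omitted", key)
            continue
        labels.append(key)
        groups.append(vals)
    return labels, groups


def run_q_battery(
    breath_df: pd.DataFrame,
    rd_df: pd.DataFrame,
    ee_profile_df: pd.DataFrame | None = None,
    rd_value: str = "rd_pct_eelv",
    alpha: float = 0.05,
) -> QBatteryReport:
    """Run Q1-Q5 on the per-breath mechanics and R/D tables.

    ``ee_profile_df`` (one row per breath with end-expiratory compartment
    quantities and a ``peep`` column) enables Q2; without it that section is
    skipped with a log entry.  Sections that lack their inputs are skipped
    by name rather than failing the whole battery.
    """
    rep = QBatteryReport()
    rep.notes.append(
        "TV is reported in litres throughout; the drive regressions assume "
        "that unit."
    )

    # ---- Q1: drive vs PEEP -------------------------------------------------
    bd = breath_df.dropna(subset=["peep"])
    if len(bd) >= 3 and bd["peep"].nunique() >= 2:
        q1 = {
            "rr_fit": fit_regression(bd["peep"].to_numpy(), bd["rr_local"].to_numpy(), 1),
            "tv_fit": fit_regression(bd["peep"].to_numpy(), bd["tv"].to_numpy(), 1),
        }
        if "subject" in bd.columns and bd["subject"].nunique() > 1:
            per = {}
            for s, g in bd.groupby("subject"):
                per[s] = {
                    "rr_fit": fit_regression(g["peep"].to_numpy(), g["rr_local"].to_numpy(), 1),
                    "tv_fit": fit_regression(g["peep"].to_numpy(), g["tv"].to_numpy(), 1),
                }
            q1["per_subject"] = per
        rep.sections["q1"] = q1
    else:
        logger.warning("run_q_battery: Q1 skipped (insufficient breath data)")

    # ---- Q2: compartments between PEEP extremes ---------------------------
    if ee_profile_df is not None and not ee_profile_df.empty:
        prof = ee_profile_df.copy()
        if "non_pct_eelw" not in prof.columns and {"non_g", "tissue_weight_g"} <= set(prof.columns):
            prof["non_pct_eelw"] = 100.0 * prof["non_g"] / prof["tissue_weight_g"]
        lo, hi = prof["peep"].min(), prof["peep"].max()
        rows = []
        for col in ("non_ml", "non_g", "non_pct_eelw", "poor_ml", "normal_ml", "hyper_ml"):
            if col not in prof.columns:
                continue
            a = prof.loc[prof["peep"] == lo, col].dropna().to_numpy()
            b = prof.loc[prof["peep"] == hi, col].dropna().to_numpy()
            k = min(a.size, b.size)
            if k < 3:
                continue
            w, p = wilcoxon_paired(a[:k], b[:k])
            rows.append({"quantity": col, "peep_low": lo, "peep_high": hi,
                         "mean_low": a.mean(), "mean_high": b.mean(),
                         "W": w, "p": p, "significant": p < alpha, "n_pairs": k})
        rep.tables["q2_compartments"] = pd.DataFrame(rows)
        rep.sections["q2"] = {"peep_low": float(lo), "peep_high": float(hi)}
    else:
        logger.warning("run_q_battery: Q2 skipped (no end-expiratory profiles)")

    # ---- Q3: R/D vs PEEP (Kruskal-Wallis + Dunn-Sidak) --------------------
    if not rd_df.empty and rd_df["peep"].nunique() >= 2:
        labels_p, groups_p = _groups_by(rd_df, rd_value, ["peep"])
        h_pool, p_pool = kruskal_wallis(groups_p)
        posthoc = dunn_sidak_posthoc(groups_p, labels=labels_p, alpha=alpha)
        rep.sections["q3"] = {"kw_pooled": GroupComparison(labels_p, h_pool, p_pool,
                                                           posthoc.pairwise)}
        rep.tables["q3_table1_pairwise_peep"] = posthoc.pairwise

        labels_d, groups_d = _groups_by(rd_df, rd_value, ["peep", "direction"])
        if len(groups_d) >= 2:
            h_limb, p_limb = kruskal_wallis(groups_d)
            rep.sections["q3"]["kw_limbs"] = {"H": h_limb, "p": p_limb}
            pairs = [
                (i, j)
                for i, j in combinations(range(len(labels_d)), 2)
                if labels_d[i][0] == labels_d[j][0]
            ]
            if pairs:
                updown = dunn_sidak_posthoc(groups_d, labels=labels_d,
                                            alpha=alpha, pairs=pairs)
                rep.tables["q3_table2_up_vs_down"] = updown.pairwise
    else:
        logger.warning("run_q_battery: Q3 skipped (insufficient R/D data)")

    # ---- Q4: R/D dispersion (Ansari-Bradley) ------------------------------
    if not rd_df.empty and rd_df["peep"].nunique() >= 2:
        labels_p, groups_p = _groups_by(rd_df, rd_value, ["peep"])
        rows = []
        for i, j in combinations(range(len(labels_p)), 2):
            lo_i = i if labels_p[i] < labels_p[j] else j
            hi_j = j if lo_i == i else i
            try:
                t = ansari_bradley(groups_p[lo_i], groups_p[hi_j],
                                   alternative="greater", alpha=alpha)
            except ValueError as exc:
                logger.info("Q4 pair (%s, %s) skipped: %s",
                            labels_p[lo_i], labels_p[hi_j], exc)
                continue
            rows.append({"peep_low": labels_p[lo_i], "peep_high": labels_p[hi_j],
                         "AB": t.statistic, "p": t.p, "h": t.reject,
                         "method": t.method})
        rep.tables["q4_table3_dispersion_pairs"] = pd.DataFrame(rows)

        rows = []
        for peep, g in rd_df.groupby("peep"):
            up = g.loc[g["direction"] == "up", rd_value].dropna().to_numpy()
            dn = g.loc[g["direction"] == "down", rd_value].dropna().to_numpy()
            if up.size < 2 or dn.size < 2:
                continue
            t = ansari_bradley(up, dn, alternative="two-sided", alpha=alpha)
            rows.append({"peep": peep, "AB": t.statistic, "p": t.p,
                         "h": t.reject, "method": t.method})
        rep.tables["q4_table4_up_vs_down"] = pd.DataFrame(rows)
        rep.sections["q4"] = {
            "n_pairs": int(len(rep.tables["q4_table3_dispersion_pairs"])),
            "n_rejected": int(rep.tables["q4_table3_dispersion_pairs"]["h"].sum())
            if len(rep.tables["q4_table3_dispersion_pairs"]) else 0,
        }
    else:
        logger.warning("run_q_battery: Q4 skipped (insufficient R/D data)")

    # ---- Q5: P_TP,MAX vs PEEP ---------------------------------------------
    bd_ok = breath_df.dropna(subset=["ptp_max"])
    if "included" in bd_ok.columns:
        bd_ok = bd_ok[bd_ok["included"]]
    if len(bd_ok) >= 5 and bd_ok["peep"].nunique() >= 4:
        rep.sections["q5"] = {
            f"degree{d}": fit_regression(bd_ok["peep"].to_numpy(),
                                         bd_ok["ptp_max"].to_numpy(), d)
            for d in (1, 2, 3)
        }
    else:
        logger.warning("run_q_battery: Q5 skipped (insufficient P_TP data)")
    return rep
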