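"""Group statistics: one-way ANOVA, Tukey HSD, Wilcoxon, regressions.

The between-group stage compares PCS, CAD and CTRL on each participant-level
metric with a one-way between-subjects ANOVA, reporting partial eta-squared
(SS_between / (SS_between + SS_within)) and post-hoc power from the
noncentral F distribution with noncentrality λ = N·η²/(1−η²) at α = 0.05.
Pairwise follow-ups use Tukey's honestly significant difference
(Tukey–Kramer for unequal group sizes).  Paired sleepiness changes use the
Wilcoxon signed-rank test with zero-difference exclusion and midrank ties
(exact distribution up to n = 25, normal approximation with tie correction
beyond).  Associations between spatial variability and performance use
ordinary least squares with adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "WilcoxonResult",
    "RegressionResult",
    "anova_oneway",
    "tukey_hsd",
    "wilcoxon_signed_rank",
    "linear_regression",
    "adjust_pvalues",
]

ALPHA = 0.05
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    partial_eta2: float
    power: float  # post hoc, alpha = 0.05
    group_means: dict
    group_sds: dict
    group_ns: dict


@dataclass(frozen=True)
class TukeyResult:
    pairs: list  # (label_a, label_b)
    mean_diffs: np.ndarray  # mean_a - mean_b
    p_adjusted: np.ndarray
    significant: np.ndarray  # at alpha = 0.05


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    p: float  # two-sided
    n_pairs: int  # after zero-difference removal
    n_zero_diffs: int
    method: str  # "exact" | "normal"


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    intercept_se: float
    slopes: np.ndarray
    slope_ses: np.ndarray
    r2: float
    adjusted_r2: float
    F: float
    df_model: int
    df_resid: int
    p: float


def _clean_groups(values_by_group: dict) -> dict[str, np.ndarray]:
    out = {}
    for k, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[np.isfinite(arr)]  # listwise deletion per measure
        if arr.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2 non-missing values")
        out[str(k)] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def anova_oneway(values_by_group: dict) -> AnovaResult:
    """Classical one-way decomposition with effect size and post-hoc power.

    Missing values are dropped per group (listwise deletion for the measure
    at hand), reproducing designs where behavioural and haemodynamic
    analyses run on different complete-case counts.
    """
    groups = _clean_groups(values_by_group)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(groups)
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = 0.0 if ms_b == 0 else float("inf")
    else:
        F = ms_b / ms_w
    p = float(sst.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    denom = ss_between + ss_within
    eta2 = float(ss_between / denom) if denom > 0 else 0.0
    if 0 <= eta2 < 1:
        lam = n_total * eta2 / (1 - eta2)
        fcrit = sst.f.isf(ALPHA, df_b, df_w)
        power = float(sst.ncf.sf(fcrit, df_b, df_w, lam))
    else:
        power = 1.0
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        partial_eta2=eta2,
        power=power,
        group_means={k_: float(g.mean()) for k_, g in groups.items()},
        group_sds={k_: float(g.std(ddof=1)) for k_, g in groups.items()},
        group_ns={k_: int(g.size) for k_, g in groups.items()},
    )


def tukey_hsd(values_by_group: dict) -> TukeyResult:
    """All-pairs comparison via the studentized range (Tukey–Kramer)."""
    groups = _clean_groups(values_by_group)
    labels = list(groups)
    res = sst.tukey_hsd(*groups.values())
    pairs, diffs, ps = [], [], []
    for i, j in combinations(range(len(labels)), 2):
        pairs.append((labels[i], labels[j]))
        diffs.append(groups[labels[i]].mean() - groups[labels[j]].mean())
        ps.append(res.pvalue[i, j])
    diffs = np.asarray(diffs)
    ps = np.asarray(ps)
    return TukeyResult(
        pairs=pairs, mean_diffs=diffs, p_adjusted=ps, significant=ps < ALPHA
    )


def _signed_rank_exact_sf_table(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ by dynamic programming over sign subsets.

    ``ranks2`` holds doubled midranks (integers).  Returns the probability
    mass over achievable values of 2*W+ (index = value).
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    return dist / dist.sum()


def wilcoxon_signed_rank(pre, post) -> WilcoxonResult:
    """Paired signed-rank test on post - pre.

    Zero differences are excluded; absolute differences receive midranks.
    For n <= 25 the p-value is exact (full enumeration of the sign
    distribution via dynamic programming, equivalent to summing all 2^n
    assignments); beyond that a normal approximation with tie correction is
    used.  Two-sided p = 2 * min(P(W+ <= w), P(W+ >= w)), capped at 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must pair up")
    d = post - pre
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sst.rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)
        dist = _signed_rank_exact_sf_table(ranks2)
        w2 = int(round(2 * w_plus))
        p_le = dist[: w2 + 1].sum()
        p_ge = dist[w2:].sum()
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sst.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(
        statistic=w_plus, p=p, n_pairs=n, n_zero_diffs=n_zero, method=method
    )


def linear_regression(response, predictors) -> RegressionResult:
    """OLS with intercept; adjusted R² and the overall F test.

    ``predictors`` may be 1-D (simple regression) or (n, p).  Rows with any
    missing value are dropped.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("collinear design")
    fit = sm.OLS(y, Xc).fit()
    return RegressionResult(
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        slopes=np.asarray(fit.params[1:]),
        slope_ses=np.asarray(fit.bse[1:]),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        F=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p=float(fit.f_pvalue),
    )


def adjust_pvalues(pvalues, n_tests: int, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni adjustment: min(1, n_tests * p) per value.

    ``n_tests`` is mandatory: the size of the test family is a reporting
    decision that must be made by the caller, never defaulted.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    return np.minimum(1.0, n_tests * p)
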