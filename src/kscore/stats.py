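"""Nonparametric statistical battery for group comparisons.

Kruskal-Wallis omnibus tests, rank-biserial effect sizes, the robust
coefficient of variation (MAD/median, unscaled), OLS regressions against
demographics, Dunn's post hoc z-tests with multiplicity correction, and
Shapiro-Wilk normality checks. Library-backed where a standard routine
exists; the rank-biserial, robust CV and Dunn statistics are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError


@dataclass
class GroupComparison:
    measure: str
    group_labels: list[str]
    medians: list[float]
    iqrs: list[float]
    h_statistic: float
    p_value: float
    rank_biserial: float | None
    robust_cv: list[float | None]


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Rank-based H with tie correction; chi-square p on k-1 df.

    Identical samples carry H = 0, for which the chi-square survival
    function gives p = 1.
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ParameterError("empty group")
    if sum(a.size for a in arrays) < 3:
        raise ParameterError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sst.kruskal(*arrays)
    return float(h), float(p)


def rank_biserial(a: np.ndarray, b: np.ndarray) -> float:
    """r_s = (#pairs a>b - #pairs a<b) / (n_a * n_b); ties contribute zero.

    Positive values mean sample ``a`` is stochastically larger. Computed from
    the Mann-Whitney U statistic (which counts ties as 1/2), so it is exact
    without enumerating pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    u = sst.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(2.0 * u / (a.size * b.size) - 1.0)


def robust_cv(x: np.ndarray) -> float:
    """100 * MAD / median, with the unscaled MAD (no 1.4826 factor)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    if med == 0:
        raise ParameterError("robust CV undefined: zero median")
    mad = np.median(np.abs(x - med))
    return float(100.0 * mad / med)


def simple_linreg(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of y on x; returns (R^2, p of the slope t-test, slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need matched samples with n >= 3")
    if np.all(x == x[0]):
        raise ParameterError("constant covariate: regression undefined")
    res = sst.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope), float(res.intercept)


def dunn_posthoc(
    groups: dict[str, np.ndarray], correction: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    Returns a tidy frame with columns group_a, group_b, z, p_raw, p_adj.
    ``correction`` is any method statsmodels' ``multipletests`` accepts
    (default Holm; "bonferroni" and "fdr_bh" are the documented alternatives).
    """
    names = list(groups)
    if len(names) < 3:
        raise ParameterError(
            "Dunn post hoc needs >= 3 groups; use rank_biserial / Mann-Whitney "
            "for a two-group comparison"
        )
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size == 0 for a in arrays):
        raise ParameterError("empty group")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sst.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sst.norm.sf(abs(z))
            rows.append({"group_a": names[i], "group_b": names[j], "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=correction)[1]
    return df


def shapiro_normality(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk test, valid for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ParameterError("Shapiro-Wilk needs 3 <= n <= 5000")
    w, p = sst.shapiro(x)
    return float(w), float(p)


def compare_groups(
    measure: str, samples: dict[str, np.ndarray], effect_pair: tuple[str, str] | None = None
) -> GroupComparison:
    """Full per-measure comparison record (medians, IQRs, H/p, r_s, robust CV).

    ``effect_pair`` names the two groups the rank-biserial is computed for
    (first listed as the stochastically-larger-positive side); defaults to the
    first two groups.
    """
    names = list(samples)
    arrays = [np.asarray(samples[n], dtype=float) for n in names]
    h, p = kruskal_wallis(*arrays)
    if effect_pair is None and len(names) >= 2:
        effect_pair = (names[0], names[1])
    rs = None
    if effect_pair is not None:
        rs = rank_biserial(samples[effect_pair[0]], samples[effect_pair[1]])
    cvs: list[float | None] = []
    for a in arrays:
        try:
            cvs.append(robust_cv(a))
        except ParameterError:
            cvs.append(None)
    return GroupComparison(
        measure=measure,
        group_labels=names,
        medians=[float(np.median(a)) for a in arrays],
        iqrs=[float(np.subtract(*np.percentile(a, [75, 25]))) for a in arrays],
        h_statistic=h,
        p_value=p,
        rank_biserial=rs,
        robust_cv=cvs,
    )
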