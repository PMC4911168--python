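"""Paired nonparametric battery for site-wise rest/stress comparisons.

Operates on a tidy study table with columns
``subject, condition, site, metric, value`` (one row per measurement):

* Friedman test across sites within a condition (exact permutation null for
  small cohorts, chi-square approximation otherwise);
* Wilcoxon signed-rank for paired comparisons (exact sign-flip null up to
  n = 25 via a polynomial convolution over mid-ranks, normal approximation
  with continuity and tie correction beyond), with Bonferroni adjustment;
* Spearman rank correlation (exact permutation null up to n = 9);
* Bland-Altman agreement with the convention differences = test - reference,
  so a test method reading systematically low yields a negative bias;
* per-site/condition summaries with a Shapiro normality gate choosing the
  headline format (mean+-SD vs median (range)).

Exact p-values are defined through the permutation/sign-flip distribution of
the test statistic itself, so they agree with brute-force enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

STUDY_COLUMNS = ("subject", "condition", "site", "metric", "value")


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check tidy-table shape and flag incomplete rest/stress pairs."""
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    counts = table.groupby(["subject", "site", "metric"])["condition"].nunique()
    incomplete = counts[counts < 2]
    out = table.copy()
    out.attrs["incomplete_pairs"] = [tuple(ix) for ix in incomplete.index]
    return out


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p: float
    p_adjusted: float
    n: int
    label: str = ""
    exact: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    exact: bool = False


@dataclass
class BlandAltmanResult:
    bias: float  # mean(test - reference)
    sd: float
    loa_low: float
    loa_high: float
    n: int


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _signed_rank_exact_p(ranks: np.ndarray, t_obs: float) -> float:
    """P(min(W+, W-) <= t_obs) under the sign-flip null, via convolution.

    ``ranks`` are mid-ranks of |d| (multiples of 0.5), so the distribution of
    2*W+ lives on integers and is built exactly as a polynomial product.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w = np.arange(total + 1) / 2.0  # W+ values
    t = np.minimum(w, total / 2.0 - w)
    return float(dist[t <= t_obs + 1e-9].sum())


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, n_comparisons: int = 1, mode: str = "auto", label: str = ""
) -> ComparisonResult:
    """Paired two-sided Wilcoxon signed-rank test on x vs y.

    Zero differences are dropped; ties of |d| get mid-ranks.  The statistic
    is T = min(W+, W-).  ``mode``: "exact" (sign-flip enumeration via
    convolution), "approx" (normal with continuity and tie correction), or
    "auto" (exact for n <= 25 informative pairs).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return ComparisonResult(
            test="wilcoxon", statistic=float("nan"), p=float("nan"),
            p_adjusted=float("nan"), n=0, label=label,
            flags=["no informative pairs (all differences zero)"],
        )
    flags = []
    if n < 5:
        flags.append("fewer than 5 informative pairs")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    t_obs = min(w_plus, w_minus)
    if mode == "exact" or (mode == "auto" and n <= 25):
        p = _signed_rank_exact_p(ranks, t_obs)
        exact = True
    else:
        mu = n * (n + 1) / 4.0
        sigma2 = float(np.sum(ranks**2)) / 4.0
        if sigma2 == 0:
            p = 1.0
        else:
            z = (t_obs - mu + 0.5) / math.sqrt(sigma2)  # continuity-corrected
            p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
        exact = False
    p = min(1.0, p)
    return ComparisonResult(
        test="wilcoxon", statistic=t_obs, p=p,
        p_adjusted=min(1.0, p * n_comparisons), n=n, label=label, exact=exact, flags=flags,
    )


def wilcoxon_paired(
    table: pd.DataFrame,
    metric: str,
    grouping: dict,
    n_comparisons: int = 1,
    mode: str = "auto",
) -> ComparisonResult:
    """Paired Wilcoxon on a study table.

    ``grouping`` selects the comparison: ``{"site": "AA"}`` compares rest vs
    stress at one site; ``{"condition": "rest", "sites": ("AA", "PDA")}``
    compares two sites within one condition.
    """
    sub = table[table["metric"] == metric]
    if "site" in grouping:
        sub = sub[sub["site"] == grouping["site"]]
        piv = sub.pivot_table(index="subject", columns="condition", values="value")
        if not {"rest", "stress"} <= set(piv.columns):
            raise ValueError("need both rest and stress records")
        piv = piv.dropna(subset=["rest", "stress"])
        x, y = piv["rest"].to_numpy(), piv["stress"].to_numpy()
        label = f"{metric}@{grouping['site']}: rest vs stress"
    elif "sites" in grouping:
        a, b = grouping["sites"]
        sub = sub[sub["condition"] == grouping["condition"]]
        piv = sub.pivot_table(index="subject", columns="site", values="value")
        piv = piv.dropna(subset=[a, b])
        x, y = piv[a].to_numpy(), piv[b].to_numpy()
        label = f"{metric}[{grouping['condition']}]: {a} vs {b}"
    else:
        raise ValueError("grouping must contain 'site' or ('condition', 'sites')")
    return wilcoxon_signed_rank(x, y, n_comparisons=n_comparisons, mode=mode, label=label)


# ---------------------------------------------------------------------------
# Friedman


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-block mid-ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    dev2 = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    # tie correction from the observed blocks
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = n * k * (k + 1) / 12.0 * (1.0 - tie_term / (n * k * (k * k - 1)))
    if denom <= 0:
        return 0.0
    return dev2 / denom


def _friedman_exact_p(ranks: np.ndarray, stat_obs: float) -> float:
    """Exact permutation p by convolving per-block rank-sum distributions.

    Under the null each block's ranks are exchangeable; the distribution of
    the column rank-sum vector is built block by block (dict convolution),
    and the p-value sums the probability of sum-of-squared-deviation values
    at least as extreme as observed (the tie correction is a constant).
    """
    n, k = ranks.shape
    dist: dict[tuple, float] = {tuple([0.0] * k): 1.0}
    for row in ranks:
        perms = set(itertools.permutations(row.tolist()))
        p_each = 1.0 / len(perms)
        nxt: dict[tuple, float] = {}
        for vec, prob in dist.items():
            for perm in perms:
                key = tuple(v + r for v, r in zip(vec, perm))
                nxt[key] = nxt.get(key, 0.0) + prob * p_each
        dist = nxt
    center = n * (k + 1) / 2.0
    dev2_obs = None
    # recompute observed on the same scale
    col_sums = ranks.sum(axis=0)
    dev2_obs = float(np.sum((col_sums - center) ** 2))
    p = 0.0
    for vec, prob in dist.items():
        dev2 = sum((v - center) ** 2 for v in vec)
        if dev2 >= dev2_obs - 1e-9:
            p += prob
    return min(1.0, p)


def friedman_sites(
    table: pd.DataFrame, metric: str, condition: str, mode: str = "auto"
) -> ComparisonResult:
    """Friedman test of site heterogeneity for one metric and condition."""
    sub = table[(table["metric"] == metric) & (table["condition"] == condition)]
    sub = sub[sub["site"] != "ALL"]
    piv = sub.pivot_table(index="subject", columns="site", values="value").dropna()
    n, k = piv.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 sites")
    if n < 2:
        raise ValueError("Friedman test needs at least 2 complete blocks")
    ranks = np.apply_along_axis(sps.rankdata, 1, piv.to_numpy())
    stat = _friedman_statistic(ranks)
    if mode == "exact" or (mode == "auto" and n <= 8):
        p = _friedman_exact_p(ranks, stat)
        exact = True
    else:
        p = float(sps.chi2.sf(stat, df=k - 1))
        exact = False
    if stat == 0.0:
        p = 1.0
    return ComparisonResult(
        test="friedman", statistic=stat, p=p, p_adjusted=p, n=n,
        label=f"{metric}[{condition}] across {list(piv.columns)}", exact=exact,
    )


# ---------------------------------------------------------------------------
# Spearman


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2) * np.sum(ry**2)))
    if denom == 0:
        return 0.0
    return float(np.dot(rx, ry) / denom)


def spearman_corr(x: np.ndarray, y: np.ndarray, mode: str = "auto") -> CorrelationResult:
    """Spearman rho on mid-ranks; exact permutation p for n <= 9, else a
    t-distribution approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if mode == "exact" or (mode == "auto" and n <= 9):
        count = 0
        total = 0
        for perm in itertools.permutations(ry.tolist()):
            total += 1
            if abs(_spearman_rho(rx, np.asarray(perm))) >= abs(rho) - 1e-9:
                count += 1
        return CorrelationResult(rho=rho, p=count / total, n=n, exact=True)
    if abs(rho) >= 1.0:
        return CorrelationResult(rho=rho, p=0.0, n=n, exact=False)
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p=min(1.0, p), n=n, exact=False)


# ---------------------------------------------------------------------------
# Bland-Altman


def bland_altman(reference: np.ndarray, test: np.ndarray) -> BlandAltmanResult:
    """Agreement of ``test`` against ``reference``: bias = mean(test - ref).

    A test method reading systematically lower than the reference therefore
    gives a negative bias.  Limits of agreement are bias +- 1.96 sd.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape or reference.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equally long")
    if reference.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = test - reference
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=diff.size
    )


# ---------------------------------------------------------------------------
# summaries


def summarize(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per site/condition summary rows with a normality-gated headline.

    Always stores mean, sd, median, min, max plus the Shapiro p; the
    ``headline`` column renders mean+-SD when Shapiro p >= 0.05 (or n < 3),
    median (range) otherwise.
    """
    sub = table[table["metric"] == metric]
    rows = []
    for (site, cond), grp in sub.groupby(["site", "condition"]):
        v = grp["value"].to_numpy(dtype=float)
        mean, sd = float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0
        med = float(np.median(v))
        vmin, vmax = float(v.min()), float(v.max())
        if v.size >= 3 and np.ptp(v) > 0:
            shapiro_p = float(sps.shapiro(v).pvalue)
        else:
            shapiro_p = float("nan")
        normal = not (shapiro_p < 0.05)  # NaN counts as normal
        headline = (
            f"{mean:.3g}±{sd:.3g}" if normal else f"{med:.3g} ({vmin:.3g}–{vmax:.3g})"
        )
        rows.append({
            "metric": metric, "site": site, "condition": cond, "n": v.size,
            "mean": mean, "sd": sd, "median": med, "min": vmin, "max": vmax,
            "shapiro_p": shapiro_p, "headline": headline,
        })
    return pd.DataFrame(rows)


def site_pair_comparisons(
    table: pd.DataFrame, metric: str, condition: str, alpha: float = 0.05
) -> list[ComparisonResult]:
    """All pairwise site Wilcoxon tests within a condition, Bonferroni-adjusted
    by the number of pairs (6 for 4 sites)."""
    sites = sorted(set(table.loc[table["site"] != "ALL", "site"]))
    pairs = list(itertools.combinations(sites, 2))
    return [
        wilcoxon_paired(
            table, metric,
            {"condition": condition, "sites": pair}, n_comparisons=len(pairs),
        )
        for pair in pairs
    ]
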