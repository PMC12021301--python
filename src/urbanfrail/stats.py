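"""Statistical layer: proportion intervals and group comparisons.

Implements the inferential toolkit the exposure table feeds into:
Wilson score intervals for category/cluster prevalences, the Yates
continuity-corrected chi-square for 2x2 proportion contrasts, one-way
ANOVA with Tukey HSD post-hoc, Kruskal–Wallis as the distribution-free
fallback, and the drivers that compare every environmental variable
(seven facility distances, the urban quality index, population density)
across frailty groups.

Test choice ("as appropriate"): ANOVA is used when every group passes a
Shapiro–Wilk normality check at alpha = 0.05, otherwise Kruskal–Wallis;
a policy argument can force either.  Tukey pairwise p-values accompany
ANOVA only.  No multiple-testing correction is applied across the nine
compared variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_spatial import UNASSIGNED
from .proximity import CATEGORIES

logger = logging.getLogger(__name__)

ALPHA = 0.05
FRAILTY_ORDER = ("robust", "prefrail", "frail")

#: Exposure-table variables compared across frailty groups.
COMPARED_VARIABLES = tuple(f"dist_{c}_m" for c in CATEGORIES) + (
    "index_value",
    "density",
)


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


# ---------------------------------------------------------------------------
# Proportions


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    conf: float
    p_hat: float
    lo: float
    hi: float

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        """(point, lo, hi) in percent, rounded for tabulation."""
        return tuple(round(100 * v, decimals) for v in (self.p_hat, self.lo, self.hi))


def wilson_ci(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    centre = (p + z^2/2n) / (1 + z^2/n),
    half-width = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n).
    No continuity correction.
    """
    if n < 1:
        raise StatsError("n must be >= 1")
    if not 0 <= k <= n:
        raise StatsError("k must be in 0..n")
    z = sps.norm.ppf(0.5 + conf / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return ProportionCI(
        k=k, n=n, conf=conf, p_hat=p,
        lo=max(0.0, centre - half), hi=min(1.0, centre + half),
    )


def chisq_yates(table) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for a 2x2 table.

    chi2 = N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2), with the correction
    floored at zero, p from the chi-square(1) upper tail.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise StatsError("table must be a nonnegative 2x2 array")
    (a, b), (c, d) = t
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise StatsError("chi-square undefined: a table margin is zero")
    num = max(abs(a * d - b * c) - n / 2, 0.0)
    stat = n * num**2 / (r1 * r2 * c1 * c2)
    return float(stat), float(sps.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class GroupComparisonResult:
    """Omnibus comparison of one variable across named groups."""

    variable: str
    groups: list[str]
    ns: list[int]
    means: list[float]
    ses: list[float]  # sd / sqrt(n) per group
    test: str  # "anova" | "kruskal-wallis"
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _summaries(groups: list[np.ndarray]) -> tuple[list[int], list[float], list[float]]:
    ns = [len(g) for g in groups]
    means = [float(np.mean(g)) for g in groups]
    ses = [float(np.std(g, ddof=1) / np.sqrt(len(g))) for g in groups]
    return ns, means, ses


def anova_tukey(
    groups: list[np.ndarray], names: list[str] | None = None, variable: str = ""
) -> GroupComparisonResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise p-values."""
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise StatsError("every group needs n >= 2")
    names = names or [f"group{i}" for i in range(len(groups))]
    f, p = sps.f_oneway(*groups)
    hsd = sps.tukey_hsd(*groups)
    pairwise = {
        (names[i], names[j]): float(hsd.pvalue[i, j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    }
    ns, means, ses = _summaries(groups)
    return GroupComparisonResult(
        variable=variable, groups=list(names), ns=ns, means=means, ses=ses,
        test="anova", statistic=float(f), p_value=float(p), pairwise=pairwise,
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    All values identical across groups is treated as no evidence of a
    difference: (H, p) = (0, 1).
    """
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    if sum(len(g) for g in groups) < 3:
        raise StatsError("need at least 3 observations in total")
    concat = np.concatenate(groups)
    if np.all(concat == concat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _choose_test(groups: list[np.ndarray], policy: str) -> str:
    if policy == "anova":
        return "anova"
    if policy == "kw":
        return "kruskal-wallis"
    if policy != "auto":
        raise StatsError(f"unknown test policy {policy!r} (use auto/anova/kw)")
    for g in groups:
        if len(g) < 3:  # Shapiro needs n >= 3; treat tiny groups as non-normal
            return "kruskal-wallis"
        if sps.shapiro(g).pvalue < ALPHA:
            return "kruskal-wallis"
    return "anova"


def compare_by_frailty(
    exposure: pd.DataFrame, variable: str, policy: str = "auto"
) -> GroupComparisonResult:
    """Compare one exposure variable across frailty categories.

    Splits ``variable`` by the ``category`` column (robust / prefrail /
    frail, in that order; absent categories are dropped with a warning),
    picks ANOVA + Tukey or Kruskal–Wallis per ``policy``, and reports
    per-group mean and standard error alongside the omnibus test.
    """
    if variable not in exposure.columns:
        raise StatsError(f"variable {variable!r} not in the exposure table")
    names = [c for c in FRAILTY_ORDER if (exposure["category"] == c).any()]
    if len(names) < len(FRAILTY_ORDER):
        missing = set(FRAILTY_ORDER) - set(names)
        logger.warning("frailty categories absent from cohort: %s", sorted(missing))
    if len(names) < 2:
        raise StatsError("need at least two nonempty frailty groups")
    groups = [
        exposure.loc[exposure["category"] == c, variable].to_numpy(float)
        for c in names
    ]
    test = _choose_test(groups, policy)
    logger.info("compare_by_frailty(%s): using %s", variable, test)
    if test == "anova":
        return anova_tukey(groups, names, variable=variable)
    h, p = kruskal_wallis(groups)
    ns, means, ses = _summaries(groups)
    return GroupComparisonResult(
        variable=variable, groups=names, ns=ns, means=means, ses=ses,
        test="kruskal-wallis", statistic=h, p_value=p,
    )


def compare_all_by_frailty(
    exposure: pd.DataFrame, policy: str = "auto"
) -> pd.DataFrame:
    """Run compare_by_frailty for all nine environmental variables.

    Returns a tidy frame: one row per variable with per-group mean (SE),
    the test used, the omnibus statistic and p-value, and Tukey pairwise
    p-values when ANOVA was used.
    """
    rows = []
    for var in COMPARED_VARIABLES:
        r = compare_by_frailty(exposure, var, policy=policy)
        row: dict = {"variable": var, "test": r.test,
                     "statistic": r.statistic, "p_value": r.p_value}
        for g, n, m, se in zip(r.groups, r.ns, r.means, r.ses):
            row[f"{g}_n"] = n
            row[f"{g}_mean"] = m
            row[f"{g}_se"] = se
        for (g1, g2), p in r.pairwise.items():
            row[f"tukey_{g1}_vs_{g2}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prevalence tables


def cluster_distribution_table(exposure: pd.DataFrame) -> pd.DataFrame:
    """Distribution of each frailty category across clusters.

    For every frailty category, the percentage of that category's
    members living in each cluster, with Wilson 95% CIs (columns sum to
    100 up to rounding).  The per-cluster p-value compares the cluster's
    membership proportion across the categories: Yates-corrected
    chi-square when only two categories are present, plain Pearson
    chi-square otherwise (the continuity correction is a 2x2 device).
    Unassigned residences are excluded.
    """
    e = exposure[exposure["cluster_id"] != UNASSIGNED]
    cats = [c for c in FRAILTY_ORDER if (e["category"] == c).any()]
    if not cats:
        raise StatsError("no frailty categories present")
    for c in set(FRAILTY_ORDER) - set(cats):
        logger.warning("category %r empty; column omitted", c)
    clusters = sorted(e["cluster_id"].unique())
    n_by_cat = {c: int((e["category"] == c).sum()) for c in cats}

    rows = []
    for cl in clusters:
        row: dict = {"cluster": cl}
        in_cluster = []
        for c in cats:
            k = int(((e["category"] == c) & (e["cluster_id"] == cl)).sum())
            ci = wilson_ci(k, n_by_cat[c])
            pct, lo, hi = ci.as_percent()
            row[f"{c}_pct"] = pct
            row[f"{c}_ci"] = f"{lo}-{hi}"
            in_cluster.append(k)
        counts = np.array([in_cluster, [n_by_cat[c] - k for c, k in zip(cats, in_cluster)]])
        if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
            p = float("nan")  # degenerate table (e.g. a single-cluster city)
        elif counts.shape == (2, 2):
            _, p = chisq_yates(counts)
        else:
            _, p, _, _ = sps.chi2_contingency(counts, correction=False)
        row["p_value"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def sociodemographic_table(exposure: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort description stratified by sex.

    Gender split with Wilson 95% CIs; age and BMI mean (SD) compared by
    the auto-gated two-group test; per-cluster prevalence within each
    sex with Wilson CIs and a Yates 2x2 chi-square per cluster.
    """
    n = len(cohort)
    rows = []
    for sex in ("female", "male"):
        k = int((cohort["sex"] == sex).sum())
        pct, lo, hi = wilson_ci(k, n).as_percent()
        rows.append(
            {"variable": f"gender_{sex}", "female": None, "male": None,
             "value": f"{pct} ({lo}-{hi})", "p_value": None}
        )
    for var in ("age", "bmi"):
        g = [cohort.loc[cohort["sex"] == s, var].to_numpy(float) for s in ("female", "male")]
        test = _choose_test(g, "auto")
        if test == "anova":
            _, p = sps.f_oneway(*g)
        else:
            _, p = kruskal_wallis(g)
        rows.append(
            {"variable": var,
             "female": f"{np.mean(g[0]):.1f} ({np.std(g[0], ddof=1):.1f})",
             "male": f"{np.mean(g[1]):.1f} ({np.std(g[1], ddof=1):.1f})",
             "value": None, "p_value": float(p)}
        )
    merged = cohort.merge(
        exposure, left_on="id", right_on="participant_id", how="left"
    )
    merged = merged[merged["cluster_id"] != UNASSIGNED]
    n_sex = {s: int((merged["sex"] == s).sum()) for s in ("female", "male")}
    for cl in sorted(merged["cluster_id"].dropna().unique()):
        cells = {}
        ks = {}
        for s in ("female", "male"):
            k = int(((merged["sex"] == s) & (merged["cluster_id"] == cl)).sum())
            ks[s] = k
            pct, lo, hi = wilson_ci(k, n_sex[s]).as_percent()
            cells[s] = f"{pct} ({lo}-{hi})"
        table = [[ks["female"], n_sex["female"] - ks["female"]],
                 [ks["male"], n_sex["male"] - ks["male"]]]
        try:
            _, p = chisq_yates(table)
        except StatsError:
            p = float("nan")
        rows.append(
            {"variable": f"cluster_{int(cl)}", "female": cells["female"],
             "male": cells["male"], "value": None, "p_value": p}
        )
    return pd.DataFrame(rows)
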