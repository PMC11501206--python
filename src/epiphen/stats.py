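"""Group statistics for phenotype tables.

The battery applied to per-animal phenotype measures: Fisher's exact test
for binary proportions, Student/Welch t and Mann-Whitney for two groups
(with the normality → variance-homogeneity auto-selection rule), two-way
ANOVA (genotype × sex, Type II sums of squares) with Tukey HSD post-hoc
comparisons, Kruskal-Wallis with Dunn's post-hoc test, Pearson correlation,
the ROUT robust outlier-removal procedure (Q = 1%), and half-up percentage
rounding as printed in results tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "compare_two",
    "anova2_tukey",
    "kruskal_dunn",
    "rout_outliers",
    "pearson_r2",
    "proportion_pct",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] of a yes/no outcome in two groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("at least one count must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 table.

    Two-sidedness follows the convention of summing the probabilities of
    all tables (with the same margins) no more probable than the observed
    one.
    """
    if isinstance(table, ContingencyTable2x2):
        table = table.as_array()
    _, p = sst.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(min(p, 1.0))


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return True
    if x.size >= 8:
        _, p = sst.normaltest(x)       # D'Agostino-Pearson
    else:
        _, p = sst.shapiro(x)
    return p >= alpha


def _variances_equal(x, y, alpha: float = 0.05) -> bool:
    """Two-sided F test on the variance ratio."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        return True
    if min(vx, vy) == 0:
        return False
    f = max(vx, vy) / min(vx, vy)
    dfn = (len(x) if vx >= vy else len(y)) - 1
    dfd = (len(y) if vx >= vy else len(x)) - 1
    p = 2 * sst.f.sf(f, dfn, dfd)
    return min(p, 1.0) >= alpha


def compare_two(x, y, mode: str = "auto") -> dict:
    """Two-group comparison: Student t, Welch t, or Mann-Whitney U.

    ``mode="auto"`` applies the selection rule used for the phenotype
    tables: parametric when both samples pass a normality test
    (D'Agostino-Pearson, Shapiro-Wilk for small n), Student when an F test
    accepts homoscedasticity and Welch otherwise; Mann-Whitney when
    normality fails.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "auto":
        if _is_normal(x) and _is_normal(y):
            mode = "student" if _variances_equal(x, y) else "welch"
        else:
            mode = "mannwhitney"
    if mode in ("student", "welch"):
        if min(x.size, y.size) < 2:
            raise ValueError("t tests need ≥2 observations per group")
        if np.array_equal(np.sort(x), np.sort(y)):
            return {"mode": mode, "statistic": 0.0, "p": 1.0}
        stat, p = sst.ttest_ind(x, y, equal_var=(mode == "student"))
    elif mode == "mannwhitney":
        stat, p = sst.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"mode": mode, "statistic": float(stat), "p": float(p)}


def anova2_tukey(table: pd.DataFrame, value: str = "value",
                 factor_a: str = "genotype", factor_b: str = "sex") -> dict:
    """Two-way ANOVA (Type II SS) with Tukey HSD over the factor cells.

    Returns F and p for both main effects and the interaction, plus
    Tukey-Kramer pairwise p-values across the ``factor_a × factor_b``
    cells computed from the model residual mean square and the studentized
    range distribution.  With zero residual variance the F statistics are
    undefined and returned as ``nan`` with ``degenerate=True``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    for fac in ("_a", "_b"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac} needs ≥2 levels")
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    mse = model.mse_resid
    scale = max(float(np.var(df["_y"])), 1.0)
    if not np.isfinite(mse) or mse <= 1e-12 * scale:
        nan = float("nan")
        return {"genotype": (nan, nan), "sex": (nan, nan),
                "interaction": (nan, nan), "tukey": {}, "degenerate": True}
    aov = sm.stats.anova_lm(model, typ=2)

    def fp(key):
        row = aov.loc[key]
        return float(row["F"]), float(row["PR(>F)"])

    cells = df.groupby(["_a", "_b"])["_y"]
    means, ns = cells.mean(), cells.size()
    k = len(means)
    dfr = model.df_resid
    tukey = {}
    labels = list(means.index)
    for i in range(k):
        for j in range(i + 1, k):
            li, lj = labels[i], labels[j]
            se = np.sqrt(mse / 2 * (1 / ns[li] + 1 / ns[lj]))
            q = abs(means[li] - means[lj]) / se
            p = float(sst.studentized_range.sf(q, k, dfr))
            tukey[(f"{li[0]}/{li[1]}", f"{lj[0]}/{lj[1]}")] = min(max(p, 0.0), 1.0)
    return {
        "genotype": fp("C(_a)"),
        "sex": fp("C(_b)"),
        "interaction": fp("C(_a):C(_b)"),
        "tukey": tukey,
        "degenerate": False,
    }


def kruskal_dunn(groups: dict, adjust: str = "bonferroni") -> dict:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise post-hoc z
    tests, Bonferroni-adjusted by default."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:   # all observations identical: no evidence
        pairs = {(names[i], names[j]): 1.0
                 for i in range(len(names)) for j in range(i + 1, len(names))}
        return {"H": 0.0, "p": 1.0, "dunn": pairs}
    h, p = sst.kruskal(*samples)

    n = pooled.size
    ranks = sst.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, s in zip(names, samples):
        mean_ranks[name] = ranks[start: start + s.size].mean()
        sizes[name] = s.size
        start += s.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (12 * (n - 1))
    m = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt((n * (n + 1) / 12 - tie_term)
                         * (1 / sizes[a] + 1 / sizes[b]))
            z = abs(mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            praw = 2 * sst.norm.sf(z)
            padj = min(praw * m, 1.0) if adjust == "bonferroni" else praw
            pairwise[(a, b)] = float(padj)
    return {"H": float(h), "p": float(p), "dunn": pairwise}


def rout_outliers(sample, q: float = 0.01) -> dict:
    """ROUT outlier removal specialized to a constant-location model.

    The robust fit is the sample median; the robust scale is the adjusted
    68.27th percentile of the absolute residuals (small-sample corrected by
    ``n/(n-1)``).  Residual t scores (df = n−1) are screened with a
    false-discovery-rate step-down at rate ``q`` from the most extreme
    point inward; flagged points are removed.

    Returns ``kept``, ``outliers`` (values) and the indices of flagged
    points in the input order.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("ROUT needs at least 3 observations")
    center = np.median(x)
    resid = x - center
    scale = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if scale == 0:
        return {"kept": x.copy(), "outliers": np.empty(0),
                "outlier_idx": np.empty(0, dtype=int)}
    t = resid / scale
    order = np.argsort(-np.abs(t))
    pvals = 2 * sst.t.sf(np.abs(t[order]), df=n - 1)
    flagged = np.zeros(n, dtype=bool)
    for rank, idx in enumerate(order):
        alpha_i = q * (n - rank) / n
        if pvals[rank] < alpha_i:
            flagged[idx] = True
        else:
            break
    return {
        "kept": x[~flagged],
        "outliers": x[flagged],
        "outlier_idx": np.flatnonzero(flagged),
    }


def pearson_r2(x, y) -> dict:
    """Pearson product-moment correlation with R² and two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need ≥3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    r, p = sst.pearsonr(x, y)
    return {"r": float(r), "r2": float(r * r), "p": float(p)}


def proportion_pct(successes: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up, as printed in results tables."""
    if not 0 <= successes <= total or total <= 0:
        raise ValueError("require 0 ≤ successes ≤ total, total > 0")
    pct = Decimal(100 * successes) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))
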