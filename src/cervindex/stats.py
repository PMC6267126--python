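"""Group-comparison statistics for cohort index tables.

The battery mirrors standard clinical-radiology practice: one-way ANOVA
with Student-Newman-Keuls (SNK) post-hoc comparisons for approximately
normal quantities, Kruskal-Wallis with an SNK-style procedure on ranks
for skewed ones, uncorrected Pearson chi-square with partitioned pairwise
sub-tables for count data, Pearson correlation for paired continuous
variables, and "mean +/- SD" / "median (Ql, Qu)" summaries.

Omnibus distributions come from scipy.stats; the SNK stepwise logic and
the chi-square partitioning are implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PosthocResult",
    "pearson_chi_square",
    "partitioned_chi_square",
    "one_way_anova",
    "snk_test",
    "kruskal_wallis",
    "kruskal_wallis_posthoc",
    "pearson_correlation",
    "summarize",
]


@dataclass
class StatResult:
    """One hypothesis test: statistic, its kind, df and two-sided p-value."""

    statistic: float
    kind: str  # one of {"F", "H", "chi2", "r", "t", "q"}
    df: tuple[float, ...]
    pvalue: float
    alpha: float = 0.05
    label: str = ""

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


@dataclass
class PosthocResult:
    """Pairwise decisions of a multiple-comparison procedure at level alpha.

    ``significant_pairs`` holds frozensets of group labels declared
    different; ``homogeneous_subsets`` are maximal runs of ordered group
    means within which no comparison rejected.
    """

    groups: tuple[str, ...]
    significant_pairs: set[frozenset] = field(default_factory=set)
    homogeneous_subsets: list[tuple[str, ...]] = field(default_factory=list)
    alpha: float = 0.05

    def differs(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return frozenset((a, b)) in self.significant_pairs


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("contingency table counts must be finite and non-negative")
    return t


def pearson_chi_square(table) -> StatResult:
    """Uncorrected Pearson chi-square test of independence.

    Sum of (O-E)^2/E over all cells with df=(r-1)(c-1); no continuity
    correction is applied.
    """
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total; expected counts undefined")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return StatResult(statistic=float(chi2), kind="chi2", df=(float(df),), pvalue=float(p))


def partitioned_chi_square(
    table,
    alpha: float = 0.05,
    row_labels: Optional[Sequence[str]] = None,
) -> dict[frozenset, StatResult]:
    """Pairwise 2xc partitions of a (3+)xc table, Bonferroni-adjusted.

    Each pair of rows is tested with an uncorrected chi-square on its 2xc
    sub-table at level alpha/k, where k is the number of pairs.  Returns a
    mapping pair-of-row-labels -> StatResult whose ``alpha`` is already
    the adjusted level.
    """
    t = _as_table(table)
    r = t.shape[0]
    if r < 3:
        raise ValueError(
            "partitioning needs at least 3 rows; use pearson_chi_square for 2 groups"
        )
    labels = tuple(row_labels) if row_labels is not None else tuple(str(i) for i in range(r))
    if len(labels) != r:
        raise ValueError("row_labels length mismatch")
    pairs = list(itertools.combinations(range(r), 2))
    adjusted = alpha / len(pairs)
    out: dict[frozenset, StatResult] = {}
    for i, j in pairs:
        res = pearson_chi_square(t[[i, j], :])
        res.alpha = adjusted
        res.label = f"{labels[i]} vs {labels[j]}"
        out[frozenset((labels[i], labels[j]))] = res
    return out


# ---------------------------------------------------------------------------
# ANOVA and the Student-Newman-Keuls procedure
# ---------------------------------------------------------------------------

def _clean_groups(groups: Sequence[Sequence[float]], min_n: int) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if any(a.size < min_n for a in arrs):
        raise ValueError(f"every group needs at least {min_n} finite observations")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """One-way fixed-effects ANOVA across two or more groups."""
    arrs = _clean_groups(groups, min_n=2)
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical; F undefined")
    f, p = sps.f_oneway(*arrs)
    k = len(arrs)
    n = pooled.size
    return StatResult(statistic=float(f), kind="F", df=(k - 1.0, float(n - k)), pvalue=float(p))


@lru_cache(maxsize=4096)
def _studentized_range_crit(alpha: float, p: int, df: int) -> float:
    """Cached studentized-range quantile q(1-alpha; p, df) (ppf is expensive)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, p, df))


def snk_test(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> PosthocResult:
    """Student-Newman-Keuls stepwise multiple comparison of group means.

    Means are ordered; the studentized range over each stretch of p
    adjacent ordered means is compared with q(1-alpha; p, df_error).  A
    stretch whose test fails to reject closes all comparisons inside it.
    Unequal group sizes use the harmonic mean of all group sizes, the
    convention of classical statistical packages.
    """
    arrs = _clean_groups(groups, min_n=2)
    k = len(arrs)
    if k < 2:
        raise ValueError("SNK needs at least two groups")
    labels = tuple(labels) if labels is not None else tuple(str(i + 1) for i in range(k))
    if len(labels) != k:
        raise ValueError("labels length mismatch")

    ns = np.array([a.size for a in arrs], dtype=float)
    means = np.array([a.mean() for a in arrs])
    n_total = int(ns.sum())
    df_error = n_total - k
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    mse = sse / df_error
    n_h = k / float((1.0 / ns).sum())
    se = math.sqrt(mse / n_h)

    order = np.argsort(means, kind="stable")
    sorted_labels = [labels[i] for i in order]
    sorted_means = means[order]

    significant: set[frozenset] = set()
    tested: dict[tuple[int, int], bool] = {}

    def reject(i: int, j: int) -> bool:
        key = (i, j)
        if key in tested:
            return tested[key]
        p = j - i + 1
        diff = sorted_means[j] - sorted_means[i]
        if se == 0.0:
            dec = bool(diff > 0.0)
        else:
            dec = bool(diff / se > _studentized_range_crit(alpha, p, df_error))
        tested[key] = dec
        return dec

    def step(i: int, j: int) -> None:
        if j - i < 1:
            return
        if reject(i, j):
            significant.add(frozenset((sorted_labels[i], sorted_labels[j])))
            step(i + 1, j)
            step(i, j - 1)
        # non-rejection closes the whole stretch: no inner tests

    step(0, k - 1)

    # a stretch is homogeneous when its extreme-pair test did not reject
    # (untested stretches were closed by a containing non-rejected stretch)
    def homogeneous(i: int, j: int) -> bool:
        return i == j or tested.get((i, j)) is not True

    candidates = []
    for i in range(k):
        j = k - 1
        while j > i and not homogeneous(i, j):
            j -= 1
        candidates.append((i, j))
    subsets = [
        tuple(sorted_labels[i : j + 1])
        for i, j in candidates
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in candidates)
    ]
    return PosthocResult(
        groups=tuple(sorted_labels),
        significant_pairs=significant,
        homogeneous_subsets=subsets,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H with tie correction and chi-square approximation."""
    arrs = _clean_groups(groups, min_n=1)
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        # fully tied data carry no ordering information: H = 0 by convention
        return StatResult(statistic=0.0, kind="H", df=(float(len(arrs) - 1),), pvalue=1.0)
    h, p = sps.kruskal(*arrs)
    return StatResult(statistic=float(h), kind="H", df=(float(len(arrs) - 1),), pvalue=float(p))


def kruskal_wallis_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> PosthocResult:
    """SNK-style stepwise comparison applied to pooled ranks.

    Observations are rank-transformed jointly (average ranks for ties) and
    the SNK procedure is run on the rank scores.  This is an analog of a
    rank post hoc, provided for parity with ANOVA post-hoc reporting; it
    is not a distribution-free guarantee.
    """
    arrs = _clean_groups(groups, min_n=2)
    pooled = np.concatenate(arrs)
    ranks = sps.rankdata(pooled)
    out, start = [], 0
    for a in arrs:
        out.append(ranks[start : start + a.size])
        start += a.size
    return snk_test(out, labels=labels, alpha=alpha)


# ---------------------------------------------------------------------------
# correlation and summaries
# ---------------------------------------------------------------------------

def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson r with the two-sided t-transform p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(xa, ya)
    return StatResult(statistic=float(r), kind="r", df=(float(n - 2),), pvalue=float(p))


def summarize(values: Sequence[float], style: str, quartile_method: str = "linear") -> str:
    """Format a sample as 'mean +/- SD' or 'median (Ql, Qu)' to 2 decimals.

    Quartiles default to linear interpolation between order statistics;
    any numpy percentile method name may be supplied instead.  The
    mean_sd style needs n >= 2 (a sample SD is otherwise undefined).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    if style == "mean_sd":
        if v.size < 2:
            raise ValueError("mean_sd summary needs at least two observations")
        return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
    if style == "median_quartiles":
        ql, med, qu = np.percentile(v, [25, 50, 75], method=quartile_method)
        return f"{med:.2f} ({ql:.2f}, {qu:.2f})"
    raise ValueError(f"unknown summary style {style!r}")
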