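"""Exact small-sample statistics: odds ratio, Fisher's exact test,
Mann-Whitney U and Wilcoxon signed-rank.

Each rank test carries a genuinely exact path (full enumeration of the
permutation distribution) used when the sample is small and tie-free, and
a normal approximation otherwise; ``TestResult.method`` records which path
produced the p-value. Two-sided exact p-values double the smaller tail
(capped at 1) for the rank tests and sum <=-likely tables for Fisher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from cd8mir.io_core import Cd8mirError, ValidationError

#: relative tolerance when comparing hypergeometric point probabilities
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d; rows = group, columns = attribute yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    exact: bool
    n: tuple[int, ...]


def odds_ratio(t: ContingencyTable2x2, haldane: bool = False):
    """Cross-product odds ratio (a*d)/(b*c); Haldane adds 0.5 to every cell.

    Without the Haldane correction the result is an exact
    :class:`~fractions.Fraction` so printed ratios like 99/20 compare
    exactly; with it, a float.
    """
    if haldane:
        a, b, c, d = t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5
        return (a * d) / (b * c)
    if t.b * t.c == 0:
        raise Cd8mirError("odds ratio undefined (zero denominator); use haldane=True")
    from fractions import Fraction

    return Fraction(t.a * t.d, t.b * t.c)


def log_or_ci(t: ContingencyTable2x2, alpha: float = 0.05) -> tuple[float, float]:
    """Woolf log-OR confidence interval (convenience)."""
    or_ = odds_ratio(t, haldane=(0 in (t.a, t.b, t.c, t.d)))
    cells = [t.a, t.b, t.c, t.d]
    if 0 in cells:
        cells = [x + 0.5 for x in cells]
    se = math.sqrt(sum(1.0 / x for x in cells))
    z = stats.norm.ppf(1 - alpha / 2)
    return or_ * math.exp(-z * se), or_ * math.exp(z * se)


def fisher_exact(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test by full hypergeometric enumeration.

    p = sum over all tables with the observed margins whose point
    probability is <= the observed table's (within relative tolerance).
    """
    r1 = t.a + t.b
    r2 = t.c + t.d
    c1 = t.a + t.c
    n = t.total
    if min(r1, r2, c1, t.b + t.d) == 0:
        # degenerate margin: only one table possible
        return TestResult(statistic=math.nan, p_two_sided=1.0, method="fisher-exact", exact=True, n=(n,))
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(stats.hypergeom.pmf(t.a, n, r1, c1))
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_REL_TOL)].sum())
    stat = float(odds_ratio(t, haldane=(t.b * t.c == 0)))
    return TestResult(
        statistic=stat, p_two_sided=min(p, 1.0), method="fisher-exact", exact=True, n=(n,)
    )


def _two_sided_from_distribution(counts: dict[float, int], observed: float) -> float:
    """Double the smaller tail of an enumerated statistic distribution, cap at 1."""
    total = sum(counts.values())
    lower = sum(c for v, c in counts.items() if v <= observed + 1e-12)
    upper = sum(c for v, c in counts.items() if v >= observed - 1e-12)
    return min(1.0, 2.0 * min(lower, upper) / total)


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney_u(
    x, y, exact_max_n: int = 25
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact path: full enumeration of all C(nx+ny, nx) group labelings of
    the pooled sample (used when nx+ny <= exact_max_n and there are no
    ties across the pooled data). Otherwise: normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    if nx + ny <= exact_max_n and not _has_ties(pooled):
        order = np.argsort(pooled)
        rank_of = np.empty(nx + ny)
        rank_of[order] = np.arange(1, nx + ny + 1)
        counts: dict[float, int] = {}
        for idx in combinations(range(nx + ny), nx):
            u = float(rank_of[list(idx)].sum() - nx * (nx + 1) / 2.0)
            counts[u] = counts.get(u, 0) + 1
        p = _two_sided_from_distribution(counts, u_x)
        return TestResult(statistic=u_x, p_two_sided=p, method="exact-enumeration", exact=True, n=(nx, ny))

    # normal approximation with tie correction and continuity correction
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(statistic=u_x, p_two_sided=1.0, method="normal-approx", exact=False, n=(nx, ny))
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return TestResult(statistic=u_x, p_two_sided=min(p, 1.0), method="normal-approx", exact=False, n=(nx, ny))


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (n reduced). Exact path enumerates all
    2^n sign assignments when n <= exact_max_n and the |diffs| are
    tie-free; otherwise a normal approximation with tie correction is
    used. All-zero input returns p = 1 with statistic 0.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_two_sided=1.0, method="all-zero", exact=True, n=(0,))
    absd = np.abs(d)
    ranks = rankdata(absd)
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n and not _has_ties(absd):
        counts: dict[float, int] = {}
        sorted_ranks = np.sort(ranks)
        for signs in range(1 << n):
            w = 0.0
            for i in range(n):
                if signs >> i & 1:
                    w += sorted_ranks[i]
            counts[w] = counts.get(w, 0) + 1
        p = _two_sided_from_distribution(counts, w_plus)
        return TestResult(statistic=w_plus, p_two_sided=p, method="exact-enumeration", exact=True, n=(n,))

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult(statistic=w_plus, p_two_sided=1.0, method="normal-approx", exact=False, n=(n,))
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return TestResult(statistic=w_plus, p_two_sided=min(p, 1.0), method="normal-approx", exact=False, n=(n,))
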