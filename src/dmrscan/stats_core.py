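"""Statistical primitives the pipeline is built on.

All decisions downstream of the count data run through this module: the
two-tailed Fisher exact test on pooled 2x2 tables, the Pearson chi-squared
heterogeneity test across replicates, Benjamini-Hochberg FDR adjustment,
the (r+1)/(n+1) empirical permutation p-value, and a Welch t-test on
arcsine-transformed proportions for cohort-level methylation comparisons.

The Fisher test uses the minimum-likelihood two-tailed definition: the
p-value sums, over the hypergeometric distribution fixed at the observed
margins, the probabilities of all tables no more probable than the
observed one.  Tables with grand total <= ``_EXACT_TOTAL_MAX`` are
evaluated in exact integer arithmetic (the p-value is then a correctly
rounded rational); larger tables use log-gamma probabilities with a
1e-7 relative tie tolerance, the convention used by R's fisher.test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "fisher_two_tailed",
    "fisher_two_tailed_many",
    "chi2_heterogeneity",
    "chi2_heterogeneity_many",
    "bh_fdr",
    "empirical_p",
    "arcsine_t_test",
]

# exact integer path bound: ~100 comb() evaluations per table, still fast
_EXACT_TOTAL_MAX = 200
_TIE_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups and columns = methylated/unmethylated."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


def _fisher_exact_int(a: int, b: int, c: int, d: int) -> float:
    """Exact rational minimum-likelihood p for small tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs_num = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(lo, hi + 1):
        num = comb(r1, k) * comb(r2, c1 - k)
        if num <= obs_num:
            total += num
    return min(1.0, total / comb(n, c1))


def _fisher_loggamma(a: int, b: int, c: int, d: int) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
        + gammaln(c1 + 1)
        + gammaln(n - c1 + 1)
        - gammaln(n + 1)
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_REL_TOL].sum()))


def fisher_two_tailed(table: ContingencyTable2x2 | tuple[int, int, int, int]) -> float:
    """Two-tailed Fisher exact test p-value in (0, 1].

    A degenerate table (any zero row or column margin) carries no
    information about association and returns p = 1 exactly.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    if a + b + c + d <= _EXACT_TOTAL_MAX:
        return _fisher_exact_int(a, b, c, d)
    return _fisher_loggamma(a, b, c, d)


def fisher_two_tailed_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorised fisher_two_tailed over parallel count arrays."""
    a = np.asarray(a, dtype=np.int64)
    out = np.empty(a.shape, dtype=float)
    cache: dict[tuple[int, int, int, int], float] = {}
    for i, tab in enumerate(zip(a.tolist(), np.asarray(b).tolist(),
                                np.asarray(c).tolist(), np.asarray(d).tolist())):
        p = cache.get(tab)
        if p is None:
            p = fisher_two_tailed(ContingencyTable2x2(*tab))
            cache[tab] = p
        out[i] = p
    return out


def chi2_heterogeneity(rows: Sequence[tuple[int, int]]) -> tuple[float, int, float]:
    """Pearson chi-squared test of heterogeneity on an R x 2 count table.

    Rows are replicate (n_meth, n_unmeth) pairs; rows with zero total are
    dropped.  Returns (statistic, df, p) with df = R - 1 and no continuity
    correction.  A zero column margin (all methylated or all unmethylated)
    gives statistic 0, p = 1.
    """
    m = np.asarray(rows, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("expected an R x 2 matrix of counts")
    if (m < 0).any():
        raise ValueError("counts must be non-negative")
    m = m[m.sum(axis=1) > 0]
    r = m.shape[0]
    if r < 2:
        raise ValueError("insufficient replicates: need >=2 rows with reads")
    df = r - 1
    col = m.sum(axis=0)
    if (col == 0).any():
        return 0.0, df, 1.0
    row = m.sum(axis=1)
    expected = np.outer(row, col) / m.sum()
    stat = float(((m - expected) ** 2 / expected).sum())
    return stat, df, float(stats.chi2.sf(stat, df))


def chi2_heterogeneity_many(
    meth: np.ndarray, unmeth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised heterogeneity test over W windows of R replicates.

    ``meth`` and ``unmeth`` are (W, R) count arrays.  Replicate rows with
    zero reads in a window are excluded from that window's test; windows
    with fewer than two usable rows get NaN statistic and p = 1 (no
    evidence of heterogeneity is obtainable).
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    tot = meth + unmeth
    usable = tot > 0
    n_rows = usable.sum(axis=1)
    col1 = np.where(usable, meth, 0.0).sum(axis=1)
    col2 = np.where(usable, unmeth, 0.0).sum(axis=1)
    grand = col1 + col2
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = tot * (col1 / grand)[:, None]
        e2 = tot * (col2 / grand)[:, None]
        terms = np.where(usable & (e1 > 0), (meth - e1) ** 2 / e1, 0.0)
        terms += np.where(usable & (e2 > 0), (unmeth - e2) ** 2 / e2, 0.0)
    stat = terms.sum(axis=1)
    df = np.maximum(n_rows - 1, 1)
    p = stats.chi2.sf(stat, df)
    degenerate = (col1 == 0) | (col2 == 0)
    p = np.where(degenerate, 1.0, p)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(n_rows < 2, 1.0, p)
    stat = np.where(n_rows < 2, np.nan, stat)
    return stat, p


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def empirical_p(
    observed: float,
    null_values: Sequence[float] | np.ndarray,
    alternative: str = "greater",
) -> float:
    """Permutation p-value (r + 1) / (n + 1); ties count as extreme; never 0."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty permutation null")
    if alternative == "greater":
        r = int((null >= observed).sum())
    elif alternative == "less":
        r = int((null <= observed).sum())
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (r + 1) / (null.size + 1)


def arcsine_t_test(
    props_a: Sequence[float], props_b: Sequence[float]
) -> tuple[float, float, float]:
    """Two-tailed Welch t-test on arcsine-transformed proportions.

    The variance-stabilising transform x -> asin(sqrt(x)) is applied to
    each group before an unequal-variance t-test.  Returns (t, df, p).
    """
    a = np.asarray(props_a, dtype=float)
    b = np.asarray(props_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 proportions per group")
    for arr in (a, b):
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("proportions must lie in [0, 1]")
    ta = np.arcsin(np.sqrt(a))
    tb = np.arcsin(np.sqrt(b))
    if ta.std(ddof=1) == 0 and tb.std(ddof=1) == 0:
        if ta.mean() == tb.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
    res = stats.ttest_ind(ta, tb, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
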