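"""Cohort statistics: nonparametric group tests and correlations.

Group sizes in preclinical xenon-MRI cohorts are small (4-9 animals), so
group comparisons are nonparametric: Mann-Whitney U for two groups (exact
permutation P below a combined-size cutoff, tie-corrected normal
approximation above it), Kruskal-Wallis for three, gated post-hoc pairwise
Mann-Whitney tests, and Pearson correlation with a least-squares line for
metric-vs-metric association.  Alpha = 0.05 two-sided, with no multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
EXACT_MAX_N = 20  # combined-sample cutoff for exact enumeration


@dataclass
class MannWhitneyResult:
    u: float          # U statistic of the first sample
    p: float
    method: str       # "exact" or "asymptotic"
    alternative: str


@dataclass
class KruskalResult:
    h: float
    p: float
    posthoc: dict[tuple[int, int], MannWhitneyResult] = field(default_factory=dict)


@dataclass
class PearsonResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def _u_from_ranksum(ranksum: float, n1: int) -> float:
    return ranksum - n1 * (n1 + 1) / 2.0


def mann_whitney(a, b, alternative: str = "two-sided",
                 exact_max_n: int = EXACT_MAX_N) -> MannWhitneyResult:
    """Mann-Whitney U test with mid-rank ties.

    For combined n <= ``exact_max_n`` the P value is computed by exhaustive
    enumeration of all C(n, n1) group labelings of the pooled (mid-ranked)
    data, which remains exact in the presence of ties.  Larger samples use
    the tie-corrected normal approximation with continuity correction.
    Reported U is that of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks
    u1 = _u_from_ranksum(ranks[:n1].sum(), n1)

    if n1 + n2 <= exact_max_n:
        n = n1 + n2
        total = comb(n, n1)
        n_le = n_ge = 0
        for idx in combinations(range(n), n1):
            u = _u_from_ranksum(sum(ranks[i] for i in idx), n1)
            if u <= u1 + 1e-9:
                n_le += 1
            if u >= u1 - 1e-9:
                n_ge += 1
        p_le, p_ge = n_le / total, n_ge / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "less":      # a tends smaller than b
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return MannWhitneyResult(u=float(u1), p=float(p), method="exact",
                                 alternative=alternative)

    res = sps.mannwhitneyu(a, b, alternative=alternative,
                           method="asymptotic", use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             method="asymptotic", alternative=alternative)


def kruskal_wallis(groups: list, alpha: float = ALPHA,
                   posthoc: bool = True) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared P.

    If the omnibus test is significant at ``alpha``, pairwise Mann-Whitney
    post-hoc tests are run (uncorrected); otherwise the post-hoc list is
    empty.  All-identical data yield H = 0, P = 1.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return KruskalResult(h=0.0, p=1.0)
    h, p = sps.kruskal(*arrays)
    result = KruskalResult(h=float(h), p=float(p))
    if posthoc and p < alpha:
        for i, j in combinations(range(len(arrays)), 2):
            result.posthoc[(i, j)] = mann_whitney(arrays[i], arrays[j])
    return result


def pearson(x, y) -> PearsonResult:
    """Pearson r with two-sided t-distribution P and least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return PearsonResult(r=float(r), p=float(p), slope=float(fit.slope),
                         intercept=float(fit.intercept), n=int(x.size))
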