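"""Contingency-table statistics: one-sided co-occurrence tails, two-sided
Fisher's exact test, Bonferroni thresholds, and rank-based group comparison.

The one-sided tails and the two-sided Fisher test are computed in log space
(log-gamma factorials + log-sum-exp), so p-values remain meaningful far below
the smallest normal double (~1e-308); both the linear-scale value and the
natural-log value are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import mannwhitneyu


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b, c, d of a 2x2 table.

    For CPE co-occurrence: a = both elements present, b = first only,
    c = second only, d = neither; N = a + b + c + d.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")
        if self.N <= 0:
            raise ValueError("table is empty (N = 0)")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bonferroni_alpha(k: int, family_alpha: float = 0.05) -> float:
    """Corrected per-test threshold for all k*(k-1)/2 pairwise tests."""
    if k < 2:
        raise ValueError("need at least two items to form a pair")
    return family_alpha / (k * (k - 1) // 2)


@dataclass(frozen=True)
class CooccurrenceResult:
    p_co: float
    p_anti: float
    log_p_co: float
    log_p_anti: float


def cooccurrence_pvalues(table: ContingencyTable2x2) -> CooccurrenceResult:
    """One-sided hypergeometric tails for a 2x2 co-occurrence table.

    ``p_co`` is the probability, under fixed margins, of at least as many
    joint occurrences as observed:

        p_co   = sum_{i=0}^{min(N-a, b, c, N-d)} C(a+b, a+i) C(c+d, c-i) / C(N, a+c)
        p_anti = sum_{i=0}^{min(a, N-b, N-c, d)} C(c+d, c+i) C(a+b, a-i) / C(N, a+c)

    Both equal classical one-sided hypergeometric tail probabilities
    (P(X >= a) and P(X <= a) for X ~ Hypergeom(N, a+c, a+b)).
    """
    a, b, c, d, N = table.a, table.b, table.c, table.d, table.N
    log_denom = _log_comb(N, a + c)

    i_co = np.arange(0, min(N - a, b, c, N - d) + 1)
    log_terms_co = _log_comb(a + b, a + i_co) + _log_comb(c + d, c - i_co)
    log_p_co = float(logsumexp(log_terms_co) - log_denom)

    i_an = np.arange(0, min(a, N - b, N - c, d) + 1)
    log_terms_an = _log_comb(c + d, c + i_an) + _log_comb(a + b, a - i_an)
    log_p_anti = float(logsumexp(log_terms_an) - log_denom)

    return CooccurrenceResult(
        p_co=min(math.exp(log_p_co), 1.0),
        p_anti=min(math.exp(log_p_anti), 1.0),
        log_p_co=min(log_p_co, 0.0),
        log_p_anti=min(log_p_anti, 0.0),
    )


def cooccurrence_tests(
    tables: Mapping[tuple[str, str], ContingencyTable2x2],
    n_items: int | None = None,
    family_alpha: float = 0.05,
):
    """Run both one-sided tails for every pair and apply Bonferroni correction.

    ``n_items`` is the number of motifs the pairs are drawn from; when omitted
    it is inferred from the distinct names in the keys. The corrected
    threshold is ``family_alpha / (n_items*(n_items-1)/2)``.
    """
    import pandas as pd

    if n_items is None:
        names = {n for pair in tables for n in pair}
        n_items = len(names)
    alpha = bonferroni_alpha(n_items, family_alpha)
    rows = []
    for (name1, name2), table in tables.items():
        res = cooccurrence_pvalues(table)
        rows.append(
            {
                "cpe1": name1,
                "cpe2": name2,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "p_co": res.p_co,
                "p_anti": res.p_anti,
                "log_p_co": res.log_p_co,
                "log_p_anti": res.log_p_anti,
                "significant_co": res.p_co < alpha,
                "significant_anti": res.p_anti < alpha,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    df.attrs["n_tests"] = n_items * (n_items - 1) // 2
    return df


@dataclass(frozen=True)
class FisherResult:
    p: float
    log_p: float
    odds_ratio: float  # nan when a margin is zero
    odds_ratio_defined: bool


def fisher_exact_two_sided(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test, computed in log space.

    Uses the standard rule: the p-value is the total probability of all
    tables (with the observed margins) whose point probability does not
    exceed that of the observed table. A small relative slack guards the
    comparison against floating-point ties.
    """
    a, b, c, d, N = table.a, table.b, table.c, table.d, table.N
    r1, c1 = a + b, a + c
    if min(r1, c1) == 0 or r1 == N or c1 == N:
        # degenerate margin: only one table possible
        return FisherResult(p=1.0, log_p=0.0, odds_ratio=float("nan"),
                            odds_ratio_defined=False)
    k = np.arange(max(0, c1 - (N - r1)), min(r1, c1) + 1)
    log_pmf = (
        _log_comb(r1, k)
        + _log_comb(N - r1, c1 - k)
        - _log_comb(N, c1)
    )
    log_p_obs = log_pmf[k == a][0]
    keep = log_pmf <= log_p_obs + 1e-7
    log_p = float(min(logsumexp(log_pmf[keep]), 0.0))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p=math.exp(log_p), log_p=log_p, odds_ratio=odds,
                        odds_ratio_defined=math.isfinite(odds))


@dataclass(frozen=True)
class GroupComparison:
    p: float
    statistic: float
    n1: int
    n2: int
    median1: float
    median2: float
    mean1: float
    mean2: float


def compare_groups(values1: Sequence[float], values2: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison with per-group summaries.

    Small samples take scipy's exact path; larger samples use the
    tie-corrected normal approximation.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return GroupComparison(
        p=float(res.pvalue),
        statistic=float(res.statistic),
        n1=x.size,
        n2=y.size,
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        mean1=float(np.mean(x)),
        mean2=float(np.mean(y)),
    )
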