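"""Inferential statistics: rank tests, hypergeometric enrichment, BH control.

The enrichment direction of interest is over-representation, so the
hypergeometric p is the upper tail P(X >= k): summed exactly over big
integers for moderate population sizes, and in log space (gammaln +
logsumexp) for very large populations or tails below float range. Odds ratios
come from the implied 2x2 table with the Haldane 0.5 correction when a cell
is empty. The Mann-Whitney U test uses the exact null for small untied
samples and the tie/continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

#: combined sample size at or below which the exact Mann-Whitney null is used
EXACT_MW_LIMIT = 16


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail test on a 2x2-style count configuration."""

    population_size: int
    population_successes: int
    sample_size: int
    sample_successes: int
    tail_p: float
    odds_ratio: float

    def as_dict(self) -> dict:
        return {
            "N": self.population_size,
            "K": self.population_successes,
            "n": self.sample_size,
            "k": self.sample_successes,
            "tail_p": self.tail_p,
            "odds_ratio": self.odds_ratio,
        }


@dataclass(frozen=True)
class RankTestResult:
    U: float
    two_sided_p: float
    method: str  # "exact" or "normal_approx_tie_corrected"
    n1: int
    n2: int


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when n1+n2 <= 16 with no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= EXACT_MW_LIMIT and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx_tie_corrected"
    return RankTestResult(
        U=float(res.statistic),
        two_sided_p=float(min(res.pvalue, 1.0)),
        method=method,
        n1=int(a.size),
        n2=int(b.size),
    )


def _log_hypergeom_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (
        gammaln(K + 1)
        - gammaln(i + 1)
        - gammaln(K - i + 1)
        + gammaln(N - K + 1)
        - gammaln(n - i + 1)
        - gammaln(N - K - n + i + 1)
        + gammaln(n + 1)
        + gammaln(N - n + 1)
        - gammaln(N + 1)
    )


def _exact_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact integer upper-tail sum; uses the pmf's multiplicative recurrence."""
    from fractions import Fraction
    from math import comb

    upper = min(K, n)
    term = comb(K, k) * comb(N - K, n - k)
    total = term
    for i in range(k, upper):
        # t_{i+1} = t_i * (K-i)(n-i) / ((i+1)(N-K-n+i+1)); exact division
        term = term * (K - i) * (n - i) // ((i + 1) * (N - K - n + i + 1))
        total += term
    return float(Fraction(total, comb(N, n)))


#: population size above which the tail falls back to log-space summation
EXACT_TAIL_LIMIT = 100_000


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Upper-tail P(X >= k) for k successes in n draws from (N, K)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValueError(f"k={k} outside hypergeometric support for N={N}, K={K}, n={n}")
    tail_p = _exact_tail(N, K, n, k) if N <= EXACT_TAIL_LIMIT else 0.0
    if tail_p == 0.0:  # very large N, or exact value underflows a float
        upper = min(K, n)
        i = np.arange(k, upper + 1)
        tail_p = (
            float(np.exp(logsumexp(_log_hypergeom_pmf(i, N, K, n)))) if i.size else 0.0
        )
    tail_p = min(tail_p, 1.0)
    a, b_, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b_, c, d) == 0:
        a, b_, c, d = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b_ * c)
    return EnrichmentResult(N, K, n, k, tail_p, float(odds_ratio))


def bidirectional_hi_enrichment(gene_table: pd.DataFrame) -> EnrichmentResult:
    """Enrichment of bidirectional-lncRNA-bearing genes among HI genes.

    Expects boolean columns has_bidirectional and haploinsufficient; the
    population is all genes, successes are bidirectional carriers, the drawn
    sample is the haploinsufficient set.
    """
    if gene_table.empty:
        raise ValueError("gene table is empty")
    has_bid = gene_table["has_bidirectional"].astype(bool)
    hi = gene_table["haploinsufficient"].astype(bool)
    return hypergeometric_enrichment(
        N=len(gene_table),
        K=int(has_bid.sum()),
        n=int(hi.sum()),
        k=int((has_bid & hi).sum()),
    )


def proportion_control(gene_table: pd.DataFrame) -> float:
    """Fisher's exact two-sided test of housekeeping x haploinsufficient."""
    if gene_table.empty:
        raise ValueError("gene table is empty")
    hk = gene_table["housekeeping"].astype(bool)
    hi = gene_table["haploinsufficient"].astype(bool)
    table = [
        [int((hk & hi).sum()), int((hk & ~hi).sum())],
        [int((~hk & hi).sum()), int((~hk & ~hi).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def gene_set_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation per term with BH-adjusted q-values.

    Returns a frame sorted by raw p with columns term, count, pct, p, q,
    odds_ratio — the shape of a GO over-representation table.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query = set(query_genes)
    stray = query - universe_set
    if stray:
        raise ValueError(
            f"{len(stray)} query genes missing from universe (e.g. {sorted(stray)[:3]})"
        )
    N, n = len(universe_set), len(query)
    records = []
    for term, members in gene_sets.items():
        mem = set(members) & universe_set
        k = len(mem & query)
        res = hypergeometric_enrichment(N, len(mem), n, k)
        records.append(
            {
                "term": term,
                "count": k,
                "pct": 100.0 * k / n if n else 0.0,
                "p": res.tail_p,
                "odds_ratio": res.odds_ratio,
            }
        )
    df = pd.DataFrame(records)
    if df.empty:
        df["q"] = []
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values (statsmodels-backed convenience)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
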