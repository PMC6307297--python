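"""Statistical kernels vs independent oracles (enumeration, rationals, resampling)."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from heartlnc.enrichment_stats import (
    benjamini_hochberg,
    bidirectional_hi_enrichment,
    gene_set_enrichment,
    hypergeometric_enrichment,
    mann_whitney,
    proportion_control,
)


def exact_mw_p(a, b):
    """Full-labeling enumeration oracle for the two-sided exact MW p-value."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pooled.argsort().argsort() + 1  # no ties by construction
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(idx)]
        us.append(float(np.sum(r) - n1 * (n1 + 1) / 2))
    us = np.array(us)
    mu = n1 * len(b) / 2
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu)))


def exact_hypergeom_tail(N, K, n, k):
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)),
        comb(N, n),
    )


def bh_stepup(p):
    """Independent BH step-up recomputation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestMannWhitney:
    def test_textbook_case(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.U == 0
        assert res.two_sided_p == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_groups_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.two_sided_p == pytest.approx(1.0, abs=0.05)

    def test_symmetric_under_group_exchange(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=6)
        assert mann_whitney(a, b).two_sided_p == pytest.approx(
            mann_whitney(b, a).two_sided_p
        )

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            res = mann_whitney(a, b)
            assert res.method == "exact"
            assert res.two_sided_p == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_exact_and_approx_agree(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(50):
            a, b = rng.normal(size=8), rng.normal(size=8)
            exact = exact_mw_p(a, b)
            approx = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(exact - min(approx, 1.0)) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestHypergeometric:
    def test_small_exact_case(self):
        res = hypergeometric_enrichment(10, 4, 5, 4)
        assert res.tail_p == pytest.approx(6 / 252, rel=1e-12)

    def test_k_zero_gives_one(self):
        assert hypergeometric_enrichment(10, 4, 5, 0).tail_p == 1.0

    def test_matches_exact_rational_summation(self, rng):
        for _ in range(20):
            N = int(rng.integers(20, 3000))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo, hi = max(0, n + K - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            expected = float(exact_hypergeom_tail(N, K, n, k))
            if expected == 0.0:
                continue
            got = hypergeometric_enrichment(N, K, n, k).tail_p
            assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_monte_carlo_resampling(self, rng):
        draws = 100_000
        for _ in range(20):
            N = int(rng.integers(30, 400))
            K = int(rng.integers(5, N - 5))
            n = int(rng.integers(5, N - 5))
            lo, hi = max(0, n + K - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            p = hypergeometric_enrichment(N, K, n, k).tail_p
            sample = rng.hypergeometric(K, N - K, n, size=draws)
            phat = np.mean(sample >= k)
            se = np.sqrt(max(p * (1 - p), 1e-12) / draws)
            assert abs(phat - p) <= 3 * se + 1e-9

    def test_tail_monotone_in_k(self):
        ps = [hypergeometric_enrichment(50, 20, 15, k).tail_p for k in range(0, 16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 12, 5, 3)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 4, 5, 5)

    def test_log_space_path_survives_extreme_tails(self):
        res = hypergeometric_enrichment(200_000, 40_000, 1_000, 600)
        assert 0.0 < res.tail_p < 1e-100


class TestGeneLevelTests:
    def test_all_genes_haploinsufficient_forces_p_one(self):
        df = pd.DataFrame({
            "gene_id": list("abcd"),
            "has_bidirectional": [True, False, True, False],
            "haploinsufficient": [True] * 4,
            "housekeeping": [False] * 4,
        })
        assert bidirectional_hi_enrichment(df).tail_p == pytest.approx(1.0)

    def test_balanced_table_gives_fisher_p_one(self):
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "housekeeping": [True] * 20 + [False] * 20,
            "haploinsufficient": ([True] * 10 + [False] * 10) * 2,
        })
        assert proportion_control(df) == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # table [[8,2],[2,8]]: p = sum of P(X=i) over i with pmf <= pmf(8)
        df_rows = [True] * 10 + [False] * 10
        hi_rows = [True] * 8 + [False] * 2 + [True] * 2 + [False] * 8
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)],
            "housekeeping": df_rows,
            "haploinsufficient": hi_rows,
        })
        pmf = [
            Fraction(comb(10, i) * comb(10, 10 - i), comb(20, 10))
            for i in range(0, 11)
        ]
        obs = pmf[8]
        expected = float(sum(p for p in pmf if p <= obs))
        assert proportion_control(df) == pytest.approx(expected, rel=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bidirectional_hi_enrichment(pd.DataFrame())


class TestGeneSetEnrichment:
    def test_exact_query_term_ranks_first(self, rng):
        universe = [f"g{i}" for i in range(200)]
        target = set(universe[:20])
        sets = {"target": target, "noise": set(universe[50:100])}
        df = gene_set_enrichment(target, sets, universe)
        assert df.iloc[0]["term"] == "target"
        assert df.iloc[0]["count"] == 20

    def test_zero_overlap_terms_get_q_one(self):
        universe = [f"g{i}" for i in range(100)]
        sets = {"a": set(universe[50:60]), "b": set(universe[60:70])}
        df = gene_set_enrichment(set(universe[:10]), sets, universe)
        assert (df["q"] == 1.0).all()

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"gX"}, {"t": {"gX"}}, {"g1"})

    def test_bh_matches_independent_stepup(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert benjamini_hochberg(p) == pytest.approx(bh_stepup(p), rel=1e-12)

    def test_bh_q_at_least_p_and_monotone_in_rank(self, rng):
        p = rng.uniform(size=30)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
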