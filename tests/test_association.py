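import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfimpact import association as assoc
from tfimpact.formats_io import CohortData, GenomicInterval, LoopPair, SnpRecord


def exact_hypergeom_tail(N, K, n, k):
    """Independent oracle: P(X >= k) as an exact rational."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


def direct_bh_stepup(pvals, alpha=0.05):
    """Independent oracle: indices rejected by the BH step-up rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    j_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= alpha * rank / m:
            j_max = rank
    return {order[i] for i in range(j_max)}


class TestRegulatoryRegion:
    def _gene(self):
        return GenomicInterval("chr1", 1000, 3000, "g")

    def test_domain_and_loop_partner(self):
        gene = self._gene()
        domain = GenomicInterval("chr1", 0, 20_000, "d")
        loop = LoopPair(
            GenomicInterval("chr1", 1500, 2500),
            GenomicInterval("chr1", 90_000, 92_000),
        )
        region = assoc.regulatory_region(gene, [domain], [loop])
        assert domain in region
        assert GenomicInterval("chr1", 90_000, 92_000) in region

    def test_no_overlap_gives_empty_region(self):
        gene = self._gene()
        domain = GenomicInterval("chr2", 0, 20_000)
        assert assoc.regulatory_region(gene, [domain], []) == []

    def test_gene_spanning_two_domains_gets_both(self):
        gene = GenomicInterval("chr1", 19_000, 21_000)
        d1 = GenomicInterval("chr1", 0, 20_000)
        d2 = GenomicInterval("chr1", 20_000, 40_000)
        region = assoc.regulatory_region(gene, [d1, d2], [])
        assert d1 in region and d2 in region


class TestEqtl:
    def test_perfect_fit(self):
        res = assoc.eqtl_test([0, 1, 1, 2], [0, 1, 1, 2])
        assert res.slope == pytest.approx(1.0)
        assert res.p_value < 1e-8

    def test_exact_zero_slope(self):
        # expression orthogonal to dosage: t = 0 gives p = 1
        res = assoc.eqtl_test([0, 0, 2, 2], [1, -1, 1, -1])
        assert res.slope == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_dosage_degenerate(self):
        res = assoc.eqtl_test([1, 1, 1, 1], [0.1, 0.4, 0.2, 0.9])
        assert res.degenerate and res.p_value == 1.0

    def test_missing_dropped_pairwise(self):
        res = assoc.eqtl_test([0, 1, 2, np.nan], [0, 1, 2, 99.0])
        assert res.n == 3
        assert res.slope == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            assoc.eqtl_test([0, 1], [0, 1])


class TestDrugResponseGenes:
    def test_exact_and_null_genes(self):
        ec50 = pd.Series(np.arange(10, dtype=float), index=[f"s{i}" for i in range(10)])
        expr = pd.DataFrame(
            {
                "match": ec50.to_numpy(),
                "flat": np.ones(10),
                "orth": [1, -1] * 5,
            },
            index=ec50.index,
        ).T
        genes = assoc.drug_response_genes(expr, ec50)
        assert "match" in genes
        assert "flat" not in genes  # constant row excluded
        assert "orth" not in genes

    def test_null_inclusion_rate_near_alpha(self):
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(size=(1000, 60)))
            ec50 = pd.Series(rng.normal(size=60))
            rates.append(len(assoc.drug_response_genes(expr, ec50)) / 1000)
        assert abs(float(np.mean(rates)) - 0.05) <= 0.02


class TestBindingChangeSnps:
    def test_small_pool_returned_whole(self):
        pool = [f"rs{i}" for i in range(250)]
        assert assoc.binding_change_snps(pool, {}, top_k=300) == frozenset(pool)

    def test_union_of_two_scorers(self):
        pool = [f"rs{i:03d}" for i in range(800)]
        up = {s: float(i) for i, s in enumerate(pool)}
        down = {s: -float(i) for i, s in enumerate(pool)}
        out = assoc.binding_change_snps(pool, up, down, top_k=300)
        assert len(out) == 600  # disjoint top-300 lists
        assert "rs000" in out and "rs799" in out and "rs400" not in out

    def test_tie_at_rank_boundary_broken_by_id(self):
        pool = [f"rs{i:02d}" for i in range(10)]
        scores = {s: 1.0 for s in pool}  # total tie
        out = assoc.binding_change_snps(pool, scores, top_k=3)
        assert out == frozenset(["rs00", "rs01", "rs02"])

    def test_empty_pool_gives_empty_set(self):
        assert assoc.binding_change_snps([], {}, top_k=10) == frozenset()


class TestHypergeom:
    def test_worked_example(self):
        # N=10, K=4, n=5, k=3: p = 66/252
        *_, p = assoc.hypergeom_enrichment(
            [f"u{i}" for i in range(10)],
            [f"u{i}" for i in range(4)],
            [f"u{i}" for i in [0, 1, 2, 4, 5]],
        )
        assert p == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        *_, p = assoc.hypergeom_enrichment(["a", "b", "c"], ["a"], ["b"])
        assert p == pytest.approx(1.0)

    def test_certain_overlap_gives_one(self):
        # K = N: every draw overlaps fully
        universe = ["a", "b", "c", "d"]
        *_, p = assoc.hypergeom_enrichment(universe, universe, ["a", "b"])
        assert p == pytest.approx(1.0)

    def test_sets_intersected_with_universe(self):
        N, K, n, k, _ = assoc.hypergeom_enrichment(
            ["a", "b"], ["a", "zzz"], ["a", "qqq"]
        )
        assert (N, K, n, k) == (2, 1, 1, 1)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            assoc.hypergeom_enrichment([], ["a"], ["b"])

    def test_matches_exact_enumeration_all_small_universes(self):
        """scipy tail equals the exact rational oracle for every
        (N, K, n, k) with N <= 15."""
        for N in range(1, 16):
            universe = [f"u{i}" for i in range(N)]
            for K in range(N + 1):
                for n in range(N + 1):
                    lo = max(0, K + n - N)
                    for k in range(lo, min(K, n) + 1):
                        set_a = universe[:K]
                        # overlap k, remainder of B from outside A
                        set_b = universe[:k] + universe[K : K + n - k]
                        got = assoc.hypergeom_enrichment(universe, set_a, set_b)
                        assert got[:4] == (N, K, n, k)
                        assert got[4] == pytest.approx(
                            exact_hypergeom_tail(N, K, n, k), abs=1e-12
                        )

    def test_monotone_in_overlap(self):
        universe = [f"u{i}" for i in range(30)]
        set_a = universe[:12]
        last = 1.1
        for k in range(0, 11):
            set_b = universe[:k] + universe[12 : 12 + 10 - k]
            *_, p = assoc.hypergeom_enrichment(universe, set_a, set_b)
            assert p <= last + 1e-12
            last = p


class TestBhFdr:
    def test_stepup_discovery_count(self):
        q = assoc.bh_fdr([0.001, 0.01, 0.02, 0.8])
        assert (q < 0.05).sum() == 3

    def test_all_ones_no_discoveries(self):
        assert (assoc.bh_fdr([1.0] * 6) < 0.05).sum() == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            assoc.bh_fdr([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_matches_direct_stepup_oracle(self, seed, m):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=m), 3)
        q = assoc.bh_fdr(p)
        assert {i for i in range(m) if q[i] < 0.05} == direct_bh_stepup(list(p))

    def test_implied_nominal_cutoff(self):
        # 38 discoveries among 888 tests at FDR 5%
        cutoff = assoc.bh_nominal_cutoff(38, 888)
        assert float(f"{cutoff:.2g}") == pytest.approx(0.0021)


class TestUtilityScore:
    def test_degenerate_pool_equals_set(self):
        universe = [f"u{i}" for i in range(20)]
        pool = universe[:5]
        *_, p_obs = assoc.hypergeom_enrichment(universe, universe[:8], pool)
        score = assoc.impact_utility_pscore(pool, 5, universe[:8], universe, p_obs, seed=1)
        assert score == 0.0  # every control is the observed set itself

    def test_pool_smaller_than_set_rejected(self):
        with pytest.raises(ValueError):
            assoc.impact_utility_pscore(["a"], 2, ["a"], ["a", "b"], 0.5)

    def test_observed_p_one_counts_strictly_smaller(self):
        universe = [f"u{i}" for i in range(40)]
        score = assoc.impact_utility_pscore(
            universe[:20], 5, universe[10:25], universe, observed_p=1.0, seed=2
        )
        assert 0.0 <= score <= 1.0


class TestRunAllPairs:
    def _sets(self, n_tfs, n_drugs, universe):
        rng = np.random.default_rng(0)
        binding = {
            f"tf{i}": frozenset(rng.choice(universe, 8, replace=False))
            for i in range(n_tfs)
        }
        pheno = {
            f"drug{j}": frozenset(rng.choice(universe, 8, replace=False))
            for j in range(n_drugs)
        }
        return binding, pheno

    def test_panel_size(self):
        universe = [f"u{i}" for i in range(60)]
        binding, pheno = self._sets(2, 3, universe)
        results = assoc.run_all_pairs(binding, pheno, universe)
        assert len(results) == 6
        assert all(r.q_value is not None for r in results)

    def test_sorted_by_p_and_reproducible(self):
        universe = [f"u{i}" for i in range(60)]
        binding, pheno = self._sets(3, 4, universe)
        pools = {tf: sorted(universe[:30]) for tf in binding}
        r1 = assoc.run_all_pairs(binding, pheno, universe, utility_pools=pools, seed=9)
        r2 = assoc.run_all_pairs(binding, pheno, universe, utility_pools=pools, seed=9)
        assert r1 == r2
        ps = [r.p_value for r in r1]
        assert ps == sorted(ps)
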