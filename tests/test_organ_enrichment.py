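"""Exact-test variants, BH adjustment, and catalog scanning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herborgan.errors import DomainError, PipelineUsageError
from herborgan.io_formats import Catalog
from herborgan.organ_enrichment import (
    ContingencyCounts,
    bh_adjust,
    ease_p,
    enrich_catalog,
    fisher_p,
    midp,
)
from herborgan.synthetic_data import gen_catalog_and_list


def _hypergeom_pmf(x, N, K, n):
    """Closed-form pmf, independent of scipy's tail conventions."""
    if x < max(0, n - (N - K)) or x > min(K, n):
        return 0.0
    return math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)


def _tail_ge(k, N, K, n):
    return sum(_hypergeom_pmf(x, N, K, n) for x in range(k, min(K, n) + 1))


class TestContingencyCounts:
    def test_invariants_enforced(self):
        with pytest.raises(DomainError):
            ContingencyCounts(k=6, K=5, n=10, N=100)
        with pytest.raises(DomainError):
            ContingencyCounts(k=1, K=5, n=101, N=100)

    def test_fold(self):
        c = ContingencyCounts(k=5, K=10, n=20, N=100)
        assert c.fold == pytest.approx(5 / (20 * 10 / 100))


class TestEaseP:
    def test_zero_overlap_is_one(self):
        assert ease_p(ContingencyCounts(k=0, K=10, n=20, N=100)) == 1.0

    def test_single_hit_discounted_to_one(self):
        assert ease_p(ContingencyCounts(k=1, K=10, n=20, N=100)) == 1.0

    def test_equals_k_minus_one_tail_sum(self):
        c = ContingencyCounts(k=5, K=10, n=20, N=100)
        assert ease_p(c) == pytest.approx(_tail_ge(4, 100, 10, 20), rel=1e-12)

    def test_more_conservative_than_fisher(self):
        c = ContingencyCounts(k=5, K=10, n=20, N=100)
        assert ease_p(c) > fisher_p(c)


class TestMidp:
    def test_complementarity_identity(self):
        for k, K, n, N in [(0, 5, 4, 10), (2, 5, 4, 10), (4, 4, 6, 12), (3, 8, 5, 20)]:
            c = ContingencyCounts(k=k, K=K, n=n, N=N)
            assert midp(c, "enriched") + midp(c, "depleted") == pytest.approx(1.0, abs=1e-12)

    def test_maximal_overlap_half_point_mass(self):
        c = ContingencyCounts(k=4, K=4, n=6, N=12)
        assert midp(c, "enriched") == pytest.approx(
            0.5 * _hypergeom_pmf(4, 12, 4, 6), rel=1e-12
        )

    def test_against_exhaustive_enumeration(self):
        # all C(10,4) draws from a universe with a 5-gene term; observed k=2
        N, K, n, k = 10, 5, 4, 2
        term = set(range(K))
        gt = eq = 0
        total = 0
        for draw in itertools.combinations(range(N), n):
            o = len(term & set(draw))
            total += 1
            gt += o > k
            eq += o == k
        expected = (gt + 0.5 * eq) / total
        c = ContingencyCounts(k=k, K=K, n=n, N=N)
        assert midp(c, "enriched") == pytest.approx(expected, rel=1e-12)

    def test_midp_below_classical_when_point_mass_positive(self):
        c = ContingencyCounts(k=3, K=8, n=5, N=20)
        assert midp(c, "enriched") < fisher_p(c)

    def test_bad_direction(self):
        with pytest.raises(DomainError):
            midp(ContingencyCounts(k=1, K=2, n=2, N=4), "sideways")


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_step_up(self):
        # ranked p*(m/i): 0.03, 0.03, 0.03 after monotone enforcement
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms())
    def test_permutation_equivariant_and_elementwise_ge(self, pvals, rnd):
        adj = bh_adjust(pvals)
        assert all(a >= p for a, p in zip(adj, pvals))
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])

    def test_never_rejects_more_than_unadjusted(self):
        rng = np.random.default_rng(0)
        pvals = rng.uniform(0, 1, size=100) ** 2
        adj = bh_adjust(list(pvals))
        assert sum(a < 0.05 for a in adj) <= sum(p < 0.05 for p in pvals)


class TestEnrichCatalog:
    def test_perfect_overlap_ranks_first_with_maximal_fold(self, tiny_catalog):
        for method in ("ease", "fisher", "hypergeometric", "midp"):
            results = enrich_catalog(tiny_catalog.terms["blood"], tiny_catalog, method=method)
            top = results[0]
            assert top.term == "blood"
            n, N, K = top.counts.n, top.counts.N, top.counts.K
            assert top.fold == pytest.approx(N / K * top.counts.k / n)

    def test_genes_outside_universe_dropped(self, tiny_catalog, caplog):
        genes = set(tiny_catalog.terms["liver"]) | {"NOT_A_GENE"}
        with caplog.at_level("INFO"):
            results = enrich_catalog(genes, tiny_catalog)
        assert results[0].counts.n == 10
        assert "outside the universe" in caplog.text

    def test_disjoint_list_usage_error(self, tiny_catalog):
        with pytest.raises(PipelineUsageError):
            enrich_catalog({"X1", "X2"}, tiny_catalog)

    def test_depleted_direction_reported_for_avoided_term(self):
        catalog, genes, _ = gen_catalog_and_list(seed=1)
        results = enrich_catalog(genes, catalog, method="midp", test_depletion=True)
        by_term = {r.term: r for r in results}
        dep = by_term["planted_depleted"]
        assert dep.counts.k == 0 and dep.direction == "depleted"
        assert dep.significant  # K=1500 avoided by a 50-gene list is detectable

    def test_planted_term_ranks_first_quick(self):
        hits = 0
        for seed in range(10):
            catalog, genes, _ = gen_catalog_and_list(seed=seed)
            results = enrich_catalog(genes, catalog, method="hypergeometric")
            if results[0].term == "planted_enriched" and results[0].p_adj < 0.05:
                hits += 1
        assert hits == 10

    def test_adjusted_ge_raw_and_sorted(self):
        catalog, genes, _ = gen_catalog_and_list(seed=3)
        results = enrich_catalog(genes, catalog, test_depletion=True)
        assert all(r.p_adj >= r.p_raw for r in results)
        assert [r.p_adj for r in results] == sorted(r.p_adj for r in results)

    def test_exhaustive_permutation_oracle_small_universe(self):
        # p from hypergeometric tails equals the fraction of all C(N,n) lists
        # with overlap >= k, for every k; mid-p lies between the two tails
        N, K, n = 10, 4, 5
        universe = [f"G{i}" for i in range(N)]
        term = set(universe[:K])
        counts = {k: 0 for k in range(min(K, n) + 1)}
        total = 0
        for draw in itertools.combinations(universe, n):
            counts[len(term & set(draw))] += 1
            total += 1
        for k in range(min(K, n) + 1):
            frac_ge = sum(v for kk, v in counts.items() if kk >= k) / total
            frac_gt = sum(v for kk, v in counts.items() if kk > k) / total
            c = ContingencyCounts(k=k, K=K, n=n, N=N)
            assert fisher_p(c) == pytest.approx(frac_ge, rel=1e-12)
            assert frac_gt <= midp(c, "enriched") <= frac_ge
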