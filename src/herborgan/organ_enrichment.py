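"""Enrichment and depletion of a gene list against a gene→organ catalog.

For each catalog term the overlap with the query list forms a 2×2 table
summarized by ``ContingencyCounts`` (k hits, term size K, list size n,
universe N).  Three exact-test variants are offered:

* ``hypergeometric`` — classical one-sided tails, P(X >= k) / P(X <= k);
* ``ease`` — the conservative variant that discounts one gene from the
  overlap before taking the upper tail, p = P(X >= k − 1) (k = 0 gives 1);
* ``midp`` — the mid-p convention giving half weight to the observed
  outcome: P(X > k) + ½·P(X = k) (enrichment) or P(X < k) + ½·P(X = k)
  (depletion).  The two directions sum exactly to 1.

P-values are adjusted by Benjamini–Hochberg over the full family of tested
hypotheses (all terms, both directions when depletion is tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, PipelineUsageError
from .io_formats import Catalog

logger = logging.getLogger(__name__)

METHODS = ("ease", "fisher", "hypergeometric", "midp")


@dataclass(frozen=True)
class ContingencyCounts:
    """Overlap counts for one term: k hits out of a list of n, term size K, universe N."""

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise DomainError(f"need 0 <= k <= min(K, n); got {self}")
        if self.K > self.N or self.n > self.N or self.K < 0 or self.n < 0:
            raise DomainError(f"need K <= N and n <= N; got {self}")

    @property
    def fold(self) -> float:
        """Observed/expected overlap ratio k / (n·K/N)."""
        expected = self.n * self.K / self.N
        return self.k / expected if expected > 0 else 0.0


def _dist(c: ContingencyCounts) -> hypergeom:
    return hypergeom(c.N, c.K, c.n)


def fisher_p(counts: ContingencyCounts) -> float:
    """Classical one-sided upper-tail p, P(X >= k)."""
    return float(min(1.0, _dist(counts).sf(counts.k - 1)))


def ease_p(counts: ContingencyCounts) -> float:
    """Upper-tail p with one overlap gene discounted: P(X >= k − 1); k = 0 gives 1."""
    if counts.k == 0:
        return 1.0
    return float(min(1.0, _dist(counts).sf(counts.k - 2)))


def midp(counts: ContingencyCounts, direction: str = "enriched") -> float:
    """Mid-p exact tail: half weight on the observed overlap count.

    ``enriched``: P(X > k) + ½·P(X = k); ``depleted``: P(X < k) + ½·P(X = k).
    """
    d = _dist(counts)
    half = 0.5 * d.pmf(counts.k)
    if direction == "enriched":
        return float(min(1.0, d.sf(counts.k) + half))
    if direction == "depleted":
        return float(min(1.0, d.cdf(counts.k - 1) + half))
    raise DomainError(f"direction must be 'enriched' or 'depleted', got {direction!r}")


def depleted_p(counts: ContingencyCounts, method: str) -> float:
    """Lower-tail p for depletion: mid-p under ``midp``, else classical P(X <= k)."""
    if method == "midp":
        return midp(counts, "depleted")
    return float(min(1.0, _dist(counts).cdf(counts.k)))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise DomainError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term outcome: counts, fold, direction, raw and adjusted p."""

    term: str
    counts: ContingencyCounts
    fold: float
    direction: str
    p_raw: float
    p_adj: float
    significant: bool


def _enriched_pvals(ks: np.ndarray, Ks: np.ndarray, n: int, N: int, method: str) -> np.ndarray:
    """Vectorized upper-tail p-values for all terms at once."""
    if method in ("fisher", "hypergeometric"):
        return np.minimum(1.0, hypergeom.sf(ks - 1, N, Ks, n))
    if method == "ease":
        p = np.minimum(1.0, hypergeom.sf(ks - 2, N, Ks, n))
        p[ks == 0] = 1.0
        return p
    if method == "midp":
        return np.minimum(1.0, hypergeom.sf(ks, N, Ks, n) + 0.5 * hypergeom.pmf(ks, N, Ks, n))
    raise PipelineUsageError(f"unknown method {method!r}; use one of {METHODS}")


def _depleted_pvals(ks: np.ndarray, Ks: np.ndarray, n: int, N: int, method: str) -> np.ndarray:
    if method == "midp":
        return np.minimum(
            1.0, hypergeom.cdf(ks - 1, N, Ks, n) + 0.5 * hypergeom.pmf(ks, N, Ks, n)
        )
    return np.minimum(1.0, hypergeom.cdf(ks, N, Ks, n))


def enrich_catalog(
    gene_list: Iterable[str],
    catalog: Catalog,
    method: str = "midp",
    test_depletion: bool = False,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every catalog term for over-representation (and optionally depletion).

    Query genes outside the catalog universe are dropped from n with a logged
    count; an empty effective list is a usage error.  Each term reports its
    observed direction (enriched iff fold >= 1 or depletion untested) with
    that direction's p; BH adjustment runs over the whole family of tested
    hypotheses.  Results are sorted by adjusted p ascending, then fold
    descending, then term name.
    """
    if method not in METHODS:
        raise PipelineUsageError(f"unknown method {method!r}; use one of {METHODS}")
    query = set(gene_list)
    effective = query & catalog.universe
    outside = len(query) - len(effective)
    if outside:
        logger.info("enrich_catalog: dropped %d gene(s) outside the universe", outside)
    if not effective:
        raise PipelineUsageError("gene list shares no genes with the catalog universe")
    n, N = len(effective), len(catalog.universe)
    terms = sorted(catalog.terms)
    Ks = np.array([len(catalog.terms[t]) for t in terms])
    ks = np.array([len(effective & catalog.terms[t]) for t in terms])

    p_enr = _enriched_pvals(ks, Ks, n, N, method)
    family = [p_enr]
    if test_depletion:
        p_dep = _depleted_pvals(ks, Ks, n, N, method)
        family.append(p_dep)
    adj = np.asarray(bh_adjust(np.concatenate(family)))
    adj_enr = adj[: len(terms)]
    adj_dep = adj[len(terms):] if test_depletion else None

    results: list[EnrichmentResult] = []
    for i, term in enumerate(terms):
        counts = ContingencyCounts(k=int(ks[i]), K=int(Ks[i]), n=n, N=N)
        if test_depletion and counts.fold < 1.0:
            direction, p_raw, p_adj = "depleted", float(p_dep[i]), float(adj_dep[i])
        else:
            direction, p_raw, p_adj = "enriched", float(p_enr[i]), float(adj_enr[i])
        results.append(
            EnrichmentResult(
                term=term,
                counts=counts,
                fold=counts.fold,
                direction=direction,
                p_raw=p_raw,
                p_adj=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    results.sort(key=lambda r: (r.p_adj, -r.fold, r.term))
    return results
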