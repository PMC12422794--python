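"""One-sided over-representation statistics.

The enrichment test is the plain hypergeometric upper tail (one-sided
Fisher's exact test): for a query of ``n`` genes drawn from a universe of
``N``, the probability of overlapping a ``K``-gene pathway in at least the
observed ``k`` genes. Pathways with raw p below the significance gate form
the enriched set that feeds the hallmark partial scores; Benjamini-Hochberg
correction is reserved for the hallmark-level significance downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .errors import DomainError, ValidationError
from .io import GeneSetLibrary

logger = logging.getLogger(__name__)

# Floor keeping p strictly positive if scipy's survival function underflows.
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_size_N: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_k <= min(self.query_size_n, self.set_size_K)):
            raise DomainError("overlap outside [0, min(n, K)]")
        if self.set_size_K > self.universe_size_N or self.query_size_n > self.universe_size_N:
            raise DomainError("set or query larger than the universe")
        if not (0.0 < self.p_value <= 1.0):
            raise DomainError(f"p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class EnrichedSet:
    """The pathways passing the significance gate for one gene sample."""

    disease_id: str
    results: tuple[EnrichmentResult, ...]
    alpha: float

    def __post_init__(self) -> None:
        ids = [r.pathway_id for r in self.results]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate pathway ids in enriched set")
        for r in self.results:
            if not r.p_value < self.alpha:
                raise ValidationError(
                    f"{r.pathway_id}: p={r.p_value} fails the p < {self.alpha} gate"
                )

    def p_values(self) -> dict[str, float]:
        return {r.pathway_id: r.p_value for r in self.results}


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in (0, 1].

    ``k`` observed overlap, ``K`` pathway size, ``n`` query size, ``N``
    universe size. Delegates to scipy's log-space survival function, which
    is stable for large factorials.
    """
    if not (0 <= k <= min(n, K)) or K > N or n > N or min(k, K, n, N) < 0:
        raise DomainError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, _P_FLOOR))


@lru_cache(maxsize=100_000)
def _tail_table(N: int, K: int, n: int) -> np.ndarray:
    """Vector of P(X >= k) for k = 0..min(n, K); cached per (N, K, n).

    The resampling loop re-tests the same pathways against thousands of
    same-size queries, so enrichment reduces to a table lookup.
    """
    kmax = min(n, K)
    ks = np.arange(0, kmax + 1)
    p = hypergeom.sf(ks - 1, N, K, n)
    return np.minimum(1.0, np.maximum(p, _P_FLOOR))


def enrich(
    query,
    library: GeneSetLibrary,
    alpha: float = 0.001,
    disease_id: str = "",
) -> EnrichedSet:
    """Test every library pathway against a gene query and keep those with
    raw p strictly below ``alpha``, sorted by (p ascending, pathway id).

    Query genes outside the universe are dropped (with a logged count);
    an empty effective query is an error that distinguishes "no genes in
    universe" from "empty input".
    """
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha {alpha} outside (0, 1]")
    q = {str(g).strip().upper() for g in query}
    if not q:
        raise ValidationError("empty query gene set")
    bg = library.universe.as_set()
    eff = q & bg
    if not eff:
        raise ValidationError(
            f"none of the {len(q)} query genes are in the {len(bg)}-gene universe"
        )
    if len(eff) < len(q):
        logger.debug("dropped %d query genes outside the universe", len(q) - len(eff))

    N = len(library.universe)
    n = len(eff)
    hits: list[EnrichmentResult] = []
    for pid in library.sets:
        members = library.sets[pid][1]
        K = len(members)
        k = len(eff & members)
        p = float(_tail_table(N, K, n)[k])
        if p < alpha:
            hits.append(
                EnrichmentResult(
                    pathway_id=pid, overlap_k=k, set_size_K=K,
                    query_size_n=n, universe_size_N=N, p_value=p,
                )
            )
    hits.sort(key=lambda r: (r.p_value, r.pathway_id))
    return EnrichedSet(disease_id=disease_id, results=tuple(hits), alpha=alpha)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; q >= p elementwise.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0.0) | (p > 1.0)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
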