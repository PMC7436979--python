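"""Over-representation analysis of a gene list against a gene-set collection.

Two tail statistics are available: the plain hypergeometric upper tail
P(X >= k), and the conservative "ease" variant which evaluates the same
tail after discounting one overlapping gene (k replaced by max(k-1, 0)).
Multiple testing is adjusted with Benjamini-Hochberg across all tested
(k >= 1) sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Set

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "overrep_pvalue",
    "enrich",
    "top_pathways",
    "map_disease_pathways",
]

METHODS = ("hypergeometric", "ease")


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation statistics.

    k = overlap size, K = set size, n = query size, N = universe size.
    """

    set_name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    overlap: frozenset = frozenset()

    @property
    def fold_enrichment(self) -> float:
        return (self.k / self.n) / (self.K / self.N)


def overrep_pvalue(k: int, K: int, n: int, N: int, method: str = "hypergeometric") -> float:
    """Upper-tail over-representation p-value.

    hypergeometric: P(X >= k) for X ~ Hypergeom(N, K, n);
    ease: the same tail evaluated at max(k-1, 0).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if not (0 <= k <= min(K, n)) or K > N or n > N or K < 0 or n < 0:
        raise ValueError(
            f"invalid counts: k={k}, K={K}, n={n}, N={N} "
            "(need 0 <= k <= min(K, n) and K, n <= N)"
        )
    if method == "ease":
        k = max(k - 1, 0)
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    method: str = "ease",
    adjust: str = "bh",
) -> List[EnrichmentResult]:
    """Test the query list against every set in the collection.

    Query genes outside the collection's universe are dropped (with a
    logged count). One result is produced per gene set with overlap
    k >= 1; BH adjustment (if requested) spans all tested sets. Results
    are sorted by (p_adj, p_raw, -fold_enrichment, name).
    """
    if adjust not in {"none", "bh"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    query_set = set(query)
    universe = collection.universe
    effective = query_set & universe
    outside = len(query_set - universe)
    if outside:
        logger.info("dropped %d query genes outside the universe", outside)
    if not effective:
        raise ValueError("query is empty after intersecting with the universe")

    n = len(effective)
    N = len(universe)
    raw: List[EnrichmentResult] = []
    for gs in collection:
        overlap = gs.members & effective
        if not overlap:
            continue
        p = overrep_pvalue(len(overlap), len(gs.members), n, N, method=method)
        raw.append(
            EnrichmentResult(
                set_name=gs.name,
                k=len(overlap),
                K=len(gs.members),
                n=n,
                N=N,
                p_raw=p,
                p_adj=p,
                overlap=frozenset(overlap),
            )
        )
    if adjust == "bh" and raw:
        adjusted = multipletests([r.p_raw for r in raw], method="fdr_bh")[1]
        raw = [
            EnrichmentResult(
                set_name=r.set_name, k=r.k, K=r.K, n=r.n, N=r.N,
                p_raw=r.p_raw, p_adj=float(p), overlap=r.overlap,
            )
            for r, p in zip(raw, adjusted)
        ]
    raw.sort(key=lambda r: (r.p_adj, r.p_raw, -r.fold_enrichment, r.set_name))
    return raw


def top_pathways(
    results: Sequence[EnrichmentResult],
    k: int = 15,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> List[EnrichmentResult]:
    """Significant results (strict p < alpha), first ``k`` in sort order."""
    significant = [
        r
        for r in results
        if (r.p_adj if use_adjusted else r.p_raw) < alpha
    ]
    return significant[:k]


def map_disease_pathways(
    top: Sequence[EnrichmentResult], disease_pathways: Iterable[str]
) -> List[EnrichmentResult]:
    """Intersect top pathways with a disease-pathway name list.

    Matching is case-insensitive on the exact name; the order of ``top``
    is preserved.
    """
    wanted = {str(name).strip().lower() for name in disease_pathways}
    return [r for r in top if r.set_name.strip().lower() in wanted]
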