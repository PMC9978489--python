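"""Generic over-representation analysis (ORA) over user gene sets.

For a query of n genes drawn from a universe of N genes, a set with K
members in the universe and k of them in the query is scored with the
one-sided upper-tail hypergeometric probability

    p = Σ_{i=k}^{min(K, n)} C(K, i) C(N−K, n−i) / C(N, n)

and Benjamini–Hochberg FDR across the collection. Both the raw-p and
the FDR significance flags are reported (different enrichment engines
threshold on different ones); the default threshold is 0.05, i.e.
−log10 p > 1.3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import GeneSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap with query
    K: int  # set size in universe
    n: int  # query size in universe
    N: int  # universe size
    p_value: float
    fdr: float
    significant_p: bool
    significant_fdr: bool

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X ≥ k)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P(X >= k); exact and stable well past N = 1e5
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up FDR; input order preserved."""
    if len(p_values) == 0:
        return []
    if any(not (0.0 < p <= 1.0) for p in p_values):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p_values, method="fdr_bh")[1])


def run_ora(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Optional[Iterable[str]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Score every gene set against the query.

    The universe defaults to the union of the collection's members
    (made explicit because the choice changes every p-value). Query
    genes outside the universe are dropped with a warning. Results are
    sorted by p ascending with a stable name tie-break.
    """
    if universe is None:
        universe_set = set()
        for gs in collection:
            universe_set |= gs.members
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")

    query_set = set(query)
    inside = query_set & universe_set
    dropped = len(query_set) - len(inside)
    if dropped:
        logger.warning("run_ora: dropped %d query gene(s) outside the universe", dropped)

    N, n = len(universe_set), len(inside)
    results = []
    for gs in collection:
        members = gs.members & universe_set
        if not members:
            continue
        K = len(members)
        k = len(members & inside)
        p = hypergeom_test(k, K, n, N)
        results.append((gs.name, k, K, p))

    fdrs = bh_adjust([p for *_, p in results])
    out = [
        EnrichmentResult(
            set_name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            fdr=fdr,
            significant_p=p < alpha,
            significant_fdr=fdr < alpha,
        )
        for (name, k, K, p), fdr in zip(results, fdrs)
    ]
    out.sort(key=lambda r: (r.p_value, r.set_name))
    return out
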