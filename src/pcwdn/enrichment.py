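"""One-sided hypergeometric gene-set enrichment computed in log space.

Enrichment p-values for overlaps between gene sets (e.g. a carbon-source
regulon and the cell-wall-degradation network genes, or a transcription
factor's ChIP-derived targets and the network) routinely fall far below
anything a linear double can hold — the strongest overlap reported for this
network is below 10**-78, and larger universes push tails below the double
underflow threshold entirely.  All tail arithmetic here therefore stays in
natural-log space: each term of

    P(X >= k) = sum_{j=k}^{min(K, n)} C(K, j) C(N-K, n-j) / C(N, n)

is evaluated through log-gamma and the sum is combined with log-sum-exp,
so the result is exact to floating precision in log10 p for any universe
up to 10**6 genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "EnrichmentQuery",
    "EnrichmentResult",
    "log_hypergeom_upper_tail",
    "log_upper_tail_all_k",
    "enrich_sets",
]

#: default significance level for the "asterisk rule" on overlap reports
DEFAULT_ALPHA = 1e-6

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class EnrichmentQuery:
    """A 2x2 overlap query: universe N, category K, sample n, overlap k."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError(f"universe size N must be >= 0, got {self.N}")
        if not 0 <= self.K <= self.N:
            raise ValueError(f"category size violates 0 <= K <= N: K={self.K}, N={self.N}")
        if not 0 <= self.n <= self.N:
            raise ValueError(f"sample size violates 0 <= n <= N: n={self.n}, N={self.N}")
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(
                f"overlap violates 0 <= k <= min(K, n): k={self.k}, K={self.K}, n={self.n}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail enrichment of a query set within a category.

    ``log10_p`` is always defined; ``p`` is the linear probability when it is
    representable as a positive double and ``None`` otherwise.  ``fold`` is
    the ratio of observed to expected overlap fraction, ``percent`` the share
    of the query set falling in the category.
    """

    N: int
    K: int
    n: int
    k: int
    log10_p: float
    p: float | None
    fold: float
    percent: float
    significant: bool


def _log_binom(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    """ln C(a, b) via log-gamma; inputs must satisfy 0 <= b <= a."""
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def log_upper_tail_all_k(N: int, K: int, n: int) -> np.ndarray:
    """log10 P(X >= k) of Hypergeom(N, K, n) for every k in 0..min(K, n).

    A single vectorized pass: the log-pmf terms are cumulated from the top
    with log-sum-exp, giving the whole suffix-tail profile at once.
    """
    EnrichmentQuery(N, K, n, 0)
    kmax = min(K, n)
    kmin = max(0, n - (N - K))  # smallest support point
    j = np.arange(kmin, kmax + 1, dtype=float)
    log_terms = _log_binom(float(K), j) + _log_binom(float(N - K), n - j) - _log_binom(float(N), float(n))
    # suffix log-sum-exp: tail(k) = lse(terms[k:]); reverse-accumulate
    rev = log_terms[::-1]
    tails = np.logaddexp.accumulate(rev)[::-1] / _LN10
    out = np.empty(kmax + 1)
    out[kmin:] = np.minimum(tails, 0.0)  # clamp fp noise above log(1)
    out[: kmin + 1] = 0.0  # P(X >= k) = 1 exactly at or below the support floor
    return out


def log_hypergeom_upper_tail(q: EnrichmentQuery) -> float:
    """log10 of P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(log_upper_tail_all_k(q.N, q.K, q.n)[q.k])


def enrich_sets(
    query_set: set[str] | frozenset[str],
    category_set: set[str] | frozenset[str],
    universe_size: int,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``query_set`` in ``category_set``.

    ``universe_size`` is the total number of genes the two sets were drawn
    from (9758 for the N. crassa genome); it must cover their union.
    """
    query_set, category_set = set(query_set), set(category_set)
    union = len(query_set | category_set)
    if universe_size < union:
        raise ValueError(
            f"universe_size {universe_size} smaller than |query ∪ category| = {union}"
        )
    k = len(query_set & category_set)
    q = EnrichmentQuery(N=universe_size, K=len(category_set), n=len(query_set), k=k)
    log10_p = log_hypergeom_upper_tail(q)
    p = 10.0**log10_p
    fold = (k / q.n) / (q.K / q.N) if q.n and q.K else float("nan")
    percent = 100.0 * k / q.n if q.n else float("nan")
    return EnrichmentResult(
        N=q.N,
        K=q.K,
        n=q.n,
        k=q.k,
        log10_p=log10_p,
        p=p if p > 0.0 else None,
        fold=fold,
        percent=percent,
        significant=log10_p < math.log10(alpha),
    )
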