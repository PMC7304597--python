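"""Hypergeometric GO-BP over-representation test for a gene window.

A window of n GO-BP genes (after tandem collapse) is tested against the
genome-wide universe of N GO-BP genes.  For a term carried by K universe
genes and k window genes the upper-tail probability is

    P(X >= k),  X ~ Hypergeometric(N, K, n)
              = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N, n)

matching the hyperGTest of Bioconductor's GOstats (unconditional, raw P,
no multiple-testing correction — the scan filters on raw P thresholds).
Output rows use the GOstats column vocabulary (GOBPID, P-value,
OddsRatio, ExpCount, Count, Size, Term).

The tail is evaluated exactly in big-integer arithmetic whenever the
window side of the table is small (always the case for 24-gene windows);
scipy's survival function is the fallback for large n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from .genome_model import Gene, GeneCatalog

_EXACT_LIMIT = 200  # exact big-int tail while min(n, N-n) stays this small

DEFAULT_MIN_COUNT = 3

ENRICHMENT_COLUMNS = [
    "GOBPID", "P-value", "OddsRatio", "ExpCount", "Count", "Size", "Term",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """The 2x2 table behind one term's test."""

    N: int  # universe: GO-BP genes genome-wide
    K: int  # universe genes carrying the term
    n: int  # window genes after collapse
    k: int  # window genes carrying the term

    def __post_init__(self) -> None:
        if not (0 < self.N and 0 < self.K <= self.N):
            raise ValueError(f"bad universe counts N={self.N}, K={self.K}")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"bad window size n={self.n} for N={self.N}")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(
                f"bad overlap k={self.k} for n={self.n}, K={self.K}"
            )


@dataclass(frozen=True)
class EnrichmentRow:
    """One GO-BP term's test result, GOstats-style."""

    go_id: str
    p_value: float
    odds_ratio: float  # math.inf when a margin is exhausted
    exp_count: float
    count: int
    size: int
    term: str = ""


def hypergeom_upper(c: ContingencyCounts) -> float:
    """Upper-tail P(X >= k) of the hypergeometric, exact where feasible."""
    if c.k == 0:
        return 1.0
    if min(c.n, c.N - c.n) <= _EXACT_LIMIT and min(c.K, c.N - c.K) <= 10_000:
        total = sum(
            math.comb(c.K, i) * math.comb(c.N - c.K, c.n - i)
            for i in range(c.k, min(c.n, c.K) + 1)
        )
        return float(Fraction(total, math.comb(c.N, c.n)))
    return float(hypergeom.sf(c.k - 1, c.N, c.K, c.n))


def odds_ratio(c: ContingencyCounts) -> float:
    """Sample odds ratio of the 2x2 table; infinite on an exhausted margin."""
    if c.n == c.k or c.K == c.k:
        return math.inf
    return (c.k * (c.N - c.K - c.n + c.k)) / ((c.n - c.k) * (c.K - c.k))


def enrich_window(
    retained_genes: Sequence[Gene],
    catalog: GeneCatalog,
    min_count: int = DEFAULT_MIN_COUNT,
    p_threshold: float = 1.0,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Test every GO-BP term present in the (collapsed) window.

    Emits one row per term with window count >= ``min_count`` (the
    prerequisite of at least 3 genes sharing a GO-BP) and
    P <= ``p_threshold``, sorted by ascending P then term id.  The
    universe is the full genome-wide GO-BP gene set, not collapsed.
    """
    if not retained_genes:
        return []
    n = len(retained_genes)
    counts: dict[str, int] = {}
    for g in retained_genes:
        for t in g.go_bp:
            counts[t] = counts.get(t, 0) + 1
    N = catalog.universe_N
    rows: list[EnrichmentRow] = []
    for term, k in counts.items():
        if k < min_count:
            continue
        K = catalog.term_K[term]
        c = ContingencyCounts(N=N, K=K, n=n, k=k)
        p = hypergeom_upper(c)
        if p > p_threshold:
            continue
        rows.append(EnrichmentRow(
            go_id=term,
            p_value=p,
            odds_ratio=odds_ratio(c),
            exp_count=n * K / N,
            count=k,
            size=K,
            term=(term_names or {}).get(term, ""),
        ))
    rows.sort(key=lambda r: (r.p_value, r.go_id))
    return rows
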