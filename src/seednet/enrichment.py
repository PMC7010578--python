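"""Over-representation analysis of a seed list against gene-set collections.

The test is the one-sided (enrichment) Fisher exact test: with a universe of
``N`` genes of which ``n`` are seeds, a set of ``K`` genes containing ``k``
seeds has p-value ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  The
upper tail is evaluated exactly in integer arithmetic, so small p-values do
not lose precision to cancellation.  Multiplicity is handled by the
Benjamini–Hochberg step-up FDR over all sets tested in one run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .geneset_io import GeneSet, GeneSetCollection, SeedList

__all__ = [
    "ContingencyCounts",
    "EnrichmentRecord",
    "hypergeom_sf",
    "hypergeom_sf_exact",
    "enrich_term",
    "bh_adjust",
    "run_enrichment",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 margins of one term: k seeds in set, set size K, n seeds, universe N."""

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        for name in ("k", "K", "n", "N"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name}={v!r} must be a non-negative integer")
        if self.K > self.N:
            raise ValueError(f"K={self.K} > N={self.N}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} > N={self.N}")
        if self.k > min(self.K, self.n):
            raise ValueError(f"k={self.k} > min(K={self.K}, n={self.n})")


@dataclass
class EnrichmentRecord:
    set_id: str
    name: str
    counts: ContingencyCounts
    p_value: float
    seed_members: frozenset[str]
    fdr: float | None = None


def hypergeom_sf_exact(counts: ContingencyCounts) -> Fraction:
    """Exact upper-tail probability ``P(X >= k)`` as a rational number.

    Computed as ``sum_{i>=k} C(K,i) C(N-K, n-i) / C(N,n)``; exact for any
    margins Python's integers can hold.
    """
    k, K, n, N = counts.k, counts.K, counts.n, counts.N
    if k == 0:
        return Fraction(1)
    total = math.comb(N, n)
    num = 0
    for i in range(k, min(K, n) + 1):
        num += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(num, total)


def hypergeom_sf(counts: ContingencyCounts) -> float:
    """One-sided enrichment p-value ``P(X >= k)`` (float of the exact rational)."""
    return float(hypergeom_sf_exact(counts))


def _two_sided_fisher(counts: ContingencyCounts) -> float:
    # sum of all hypergeometric outcomes no more probable than the observed one
    k, K, n, N = counts.k, counts.K, counts.n, counts.N
    total = math.comb(N, n)
    lo, hi = max(0, n - (N - K)), min(K, n)
    obs = math.comb(K, k) * math.comb(N - K, n - k)
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(lo, hi + 1)
        if math.comb(K, i) * math.comb(N - K, n - i) <= obs
    )
    return float(Fraction(num, total))


def enrich_term(
    seed: SeedList,
    gene_set: GeneSet,
    universe: set[str],
    two_sided: bool = False,
) -> EnrichmentRecord:
    """Test one gene set for seed over-representation within ``universe``.

    Both the seed list and the set are intersected with the universe before
    counting, so genes without annotation do not inflate the margins.
    """
    if not universe:
        raise ValueError("universe is empty")
    set_in_u = gene_set.members & universe
    seed_in_u = seed.genes & universe
    hits = seed_in_u & set_in_u
    counts = ContingencyCounts(
        k=len(hits), K=len(set_in_u), n=len(seed_in_u), N=len(universe)
    )
    p = _two_sided_fisher(counts) if two_sided else hypergeom_sf(counts)
    return EnrichmentRecord(
        set_id=gene_set.set_id,
        name=gene_set.name,
        counts=counts,
        p_value=p,
        seed_members=frozenset(hits),
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, returned in input order.

    ``q_(i) = min_{j>=i} p_(j) * m / j`` over the ascending order statistics,
    capped at 1.
    """
    m = len(p_values)
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p_values[idx] * m / rank)
        # guard against float rounding pushing q below p (q >= p always
        # holds mathematically for the step-up)
        adjusted[idx] = max(running_min, p_values[idx])
    return adjusted


def run_enrichment(
    seed: SeedList,
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    min_seed_genes: int = 5,
    fdr_threshold: float = 0.05,
    two_sided: bool = False,
    prune_subsets: bool = False,
    keep_all: bool = False,
) -> list[EnrichmentRecord]:
    """Test every set in the collection and apply the survivor filters.

    BH adjustment runs over *all* tested sets; a record survives iff it has
    at least ``min_seed_genes`` seed members and ``fdr < fdr_threshold``.
    Survivors are sorted by ascending p, ties broken by ``set_id``.  The
    default universe is the union of all genes in the collection.
    ``keep_all=True`` skips the survivor filters and returns every tested
    record (still FDR-annotated and rank-sorted) — the form used for rank
    diagnostics.  ``prune_subsets`` optionally drops a survivor whose seed
    members are a subset of another survivor with smaller or equal p (a
    crude stand-in for semantic redundancy removal); off by default.
    """
    if not len(collection):
        raise ValueError("collection is empty")
    if min_seed_genes < 1:
        raise ValueError("min_seed_genes must be >= 1")
    if not (0.0 <= fdr_threshold <= 1.0):
        raise ValueError("fdr_threshold must be in [0, 1]")
    if universe is None:
        universe = collection.all_genes
    records = [enrich_term(seed, s, universe, two_sided=two_sided) for s in collection]
    for rec, fdr in zip(records, bh_adjust([r.p_value for r in records])):
        rec.fdr = fdr
    if keep_all:
        records.sort(key=lambda r: (r.p_value, r.set_id))
        return records
    kept = [
        r for r in records
        if r.counts.k >= min_seed_genes and r.fdr is not None and r.fdr < fdr_threshold
    ]
    kept.sort(key=lambda r: (r.p_value, r.set_id))
    if prune_subsets:
        survivors: list[EnrichmentRecord] = []
        for r in kept:  # kept is p-ascending, so earlier records dominate
            if not any(r.seed_members <= s.seed_members and r is not s
                       for s in survivors):
                survivors.append(r)
        kept = survivors
    return kept


def write_enrichment_tsv(records: Iterable[EnrichmentRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "set_id": r.set_id,
            "name": r.name,
            "k": r.counts.k,
            "K": r.counts.K,
            "n": r.counts.n,
            "N": r.counts.N,
            "p_value": f"{r.p_value:.6e}",
            "fdr": "" if r.fdr is None else f"{r.fdr:.6e}",
            "seed_members": ",".join(sorted(r.seed_members)),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["set_id", "name", "k", "K", "n", "N", "p_value", "fdr", "seed_members"],
    ).to_csv(path, sep="\t", index=False)
    return path
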