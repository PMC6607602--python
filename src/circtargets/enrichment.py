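"""Pathway over-representation and the permutation convergence test.

A selected gene list (e.g. the top common-target genes) is tested against
a gene-set collection with the one-sided hypergeometric test, adjusted by
Benjamini–Hochberg FDR; a pathway is called enriched at q <= 0.05 by
default.  Whether the *number* of enriched pathways is itself surprising
is assessed with a permutation test: equal-sized gene lists are drawn
uniformly without replacement from the full target-gene pool of the
circRNA-bound miRNAs, and the empirical p-value is

    p = (1 + #{null counts >= observed}) / (n_perm + 1),

the add-one convention, so p is never 0 and is exact under exchangeability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p: float
    q: float


@dataclass(frozen=True)
class PermutationSummary:
    observed_enriched: int
    n_perm: int
    null_counts: tuple[int, ...]
    empirical_p: float


def _sf_pairs(overlaps: np.ndarray, set_sizes: np.ndarray, N: int, n: int) -> np.ndarray:
    """Vector of upper-tail hypergeometric p-values, deduplicated.

    (overlap, set size) pairs repeat heavily across a pathway collection;
    evaluating scipy's survival function once per unique pair is much
    cheaper and numerically identical.
    """
    pairs = np.stack([overlaps, set_sizes], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    ps_uniq = hypergeom.sf(uniq[:, 0] - 1, N, uniq[:, 1], n)
    return np.asarray(ps_uniq)[inverse]


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` = overlap, ``n`` = list size, ``K`` = set size, ``N`` =
    universe size.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N and n >= 0 and K >= 0):
        raise ValueError(f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_list: Sequence[str],
    gene_sets: GeneSetCollection,
    q_threshold: float = 0.05,
    *,
    warn_outside: bool = True,
) -> tuple[list[EnrichmentRow], int]:
    """Hypergeometric over-representation of ``gene_list`` in each pathway.

    Genes outside the collection's universe are dropped (with a logged
    warning); p-values are BH-adjusted across all pathways and the number
    of pathways with q <= ``q_threshold`` is returned alongside the rows,
    which are sorted by (p, pathway_id).
    """
    universe = gene_sets.universe
    genes = set(gene_list)
    outside = genes - universe
    if outside:
        if warn_outside:
            logger.warning("dropping %d genes outside the universe", len(outside))
        genes &= universe
    if not genes:
        raise ValueError("gene list is empty after intersecting with the universe")
    N = len(universe)
    n = len(genes)
    overlaps = np.array([len(genes.intersection(s.genes)) for s in gene_sets.sets])
    set_sizes = np.array([len(frozenset(s.genes) & universe) for s in gene_sets.sets])
    ps = _sf_pairs(overlaps, set_sizes, N, n)
    qs = multipletests(ps, method="fdr_bh")[1]
    rows = [
        EnrichmentRow(
            pathway_id=s.id,
            overlap=int(k),
            set_size=int(K),
            list_size=n,
            universe_size=N,
            p=float(p),
            q=float(q),
        )
        for s, k, K, p, q in zip(gene_sets.sets, overlaps, set_sizes, ps, qs)
    ]
    rows.sort(key=lambda r: (r.p, r.pathway_id))
    enriched = sum(1 for r in rows if r.q <= q_threshold)
    return rows, enriched


def permutation_test(
    observed_enriched: int,
    list_size: int,
    full_target_genes: Sequence[str],
    gene_sets: GeneSetCollection,
    q_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermutationSummary:
    """Permutation null for the enriched-pathway count.

    Draws ``n_perm`` gene lists of ``list_size`` uniformly without
    replacement from the deduplicated ``full_target_genes`` pool, counts
    enriched pathways for each with :func:`enrich`, and reports the
    add-one empirical p-value for ``observed_enriched``.  Fully
    reproducible from ``seed``.
    """
    pool = sorted(set(full_target_genes))
    if list_size > len(pool):
        raise ValueError(
            f"list_size {list_size} exceeds target-gene pool size {len(pool)}"
        )
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    # same arithmetic as enrich(), with the per-pathway constants hoisted
    # out of the permutation loop and no report rows built
    universe = gene_sets.universe
    members = [frozenset(s.genes) & universe for s in gene_sets.sets]
    set_sizes = np.array([len(m) for m in members])
    N = len(universe)
    null_counts = []
    for _ in range(n_perm):
        draw = rng.choice(pool_arr, size=list_size, replace=False)
        genes = set(draw) & universe
        if not genes:
            raise ValueError("permutation draw fell entirely outside the universe")
        overlaps = np.array([len(genes & m) for m in members])
        ps = _sf_pairs(overlaps, set_sizes, N, len(genes))
        qs = multipletests(ps, method="fdr_bh")[1]
        null_counts.append(int((qs <= q_threshold).sum()))
    null = np.array(null_counts)
    empirical_p = float((1 + int((null >= observed_enriched).sum())) / (n_perm + 1))
    return PermutationSummary(
        observed_enriched=observed_enriched,
        n_perm=n_perm,
        null_counts=tuple(int(c) for c in null_counts),
        empirical_p=empirical_p,
    )
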