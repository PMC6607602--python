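"""Deterministic synthetic data with planted, exactly known ground truth.

Everything the pipeline consumes can be generated here without downloads:

* random mature miRNAs whose seed 7-mers are mutually non-colliding,
* a circRNA embedding exact reverse complements of chosen miRNAs at
  recorded circular coordinates, optionally with one copy split across
  the backsplice point, over a rejection-sampled background guaranteed to
  contain no stray seed match,
* a miRNA->gene interaction table with a dense co-targeting block plus
  sparse random pairs,
* a gene-set collection with one pathway planted inside the co-target
  block (so the common-target machinery has a known convergence signal),
* a separate enrichment testbed whose permutation pool overlaps pathways
  to smoothly varying degrees, giving the enriched-pathway count a
  spread-out null distribution for calibration checks.

Every generator is a pure function of its :class:`FixtureSpec` (seed
included); identical specs give identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    GeneSet,
    GeneSetCollection,
    NucleotideSequence,
    TargetInteraction,
    write_fasta,
    write_gene_sets,
    write_target_table,
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_BASES = "ACGU"


class FixtureGenerationError(RuntimeError):
    """Raised when a fixture cannot be packed or cleaned within limits."""


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _seed_7mer(mir: str) -> str:
    """The target-side seed match: reverse complement of miRNA positions 2-8."""
    return revcomp(mir[1:8])


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the standard synthetic study conditions.

    Defaults define a 1500-nt circRNA carrying 12 planted sites for 8 of
    20 miRNAs (one site split across the backsplice point), 300 genes of
    which a 20-gene block is co-targeted by the 5 highest-nbs bound
    miRNAs, sparse background targeting at rate 0.12, and 25 pathways of
    20 genes with one 15-gene pathway planted inside the block.
    """

    seed: int = 0
    n_mirnas: int = 20
    mirna_length: tuple[int, int] = (20, 23)
    circ_length: int = 1500
    # (site count, one copy spans the backsplice point) for miRNAs 0, 1, ...
    planted_sites: tuple[tuple[int, bool], ...] = (
        (3, True),
        (2, False),
        (2, False),
        (1, False),
        (1, False),
        (1, False),
        (1, False),
        (1, False),
    )
    n_genes: int = 300
    block_genes: int = 20
    block_mirnas: int = 5
    sparse_rate: float = 0.12
    n_pathways: int = 25
    pathway_size: int = 20
    n_planted_pathways: int = 3
    planted_pathway_size: int = 15
    spacer: int = 7

    def __post_init__(self) -> None:
        if len(self.planted_sites) > self.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs")
        if self.planted_pathway_size > self.block_genes:
            raise ValueError("planted pathway must fit inside the co-target block")
        if self.planted_sites and self.block_mirnas > len(self.planted_sites):
            raise ValueError("block miRNAs must be bound (planted) miRNAs")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"GENE{i:04d}" for i in range(1, self.n_genes + 1))

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(f"syn-miR-{i + 1:02d}" for i in range(self.n_mirnas))

    @property
    def bound_mirna_ids(self) -> tuple[str, ...]:
        return tuple(
            mid
            for mid, (count, _) in zip(self.mirna_ids, self.planted_sites)
            if count > 0
        )

    @property
    def block_mirna_ids(self) -> tuple[str, ...]:
        return self.bound_mirna_ids[: self.block_mirnas]

    @property
    def block_gene_ids(self) -> tuple[str, ...]:
        return self.gene_ids[: self.block_genes]


def make_mirnas(spec: FixtureSpec) -> list[NucleotideSequence]:
    """Random miRNAs with pairwise-distinct, non-colliding seed 7-mers.

    Beyond distinctness, each accepted miRNA's full-site reverse
    complement contains its own seed match exactly once and no other
    miRNA's — so a planted site can never hand a stray seed to a
    different miRNA.
    """
    rng = np.random.default_rng([spec.seed, 11])
    lo, hi = spec.mirna_length
    mirnas: list[str] = []
    while len(mirnas) < spec.n_mirnas:
        for _attempt in range(500):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
            site = revcomp(seq)
            ok = (
                seq not in mirnas
                and site.count(_seed_7mer(seq)) == 1
                and all(
                    _seed_7mer(other) not in site
                    and _seed_7mer(seq) not in revcomp(other)
                    for other in mirnas
                )
            )
            if ok:
                mirnas.append(seq)
                break
        else:
            raise FixtureGenerationError("could not draw a non-colliding miRNA set")
    return [
        NucleotideSequence(id=mid, residues=seq, topology="linear")
        for mid, seq in zip(spec.mirna_ids, mirnas)
    ]


def make_sponge_circ(
    spec: FixtureSpec, mirnas: Sequence[NucleotideSequence]
) -> tuple[NucleotideSequence, dict[str, list[tuple[int, int, bool]]]]:
    """A circRNA embedding exact complements of the planted miRNAs.

    Returns the sequence plus the ground-truth site map
    ``{mirna_id: [(start, end, spans_junction), ...]}`` in circular
    0-based half-open coordinates (``end > L`` for the split copy).
    Background residues are rejection-sampled until no seed match to any
    fixture miRNA survives outside the sanctioned planted positions.
    """
    rng = np.random.default_rng([spec.seed, 13])
    L = spec.circ_length
    chars: list[str | None] = [None] * L
    fixed = np.zeros(L, dtype=bool)  # planted residues, immutable
    blocked = np.zeros(L, dtype=bool)  # planted + spacer margin, no new sites
    ground: dict[str, list[tuple[int, int, bool]]] = {}
    sanctioned: set[tuple[int, str]] = set()  # (circular pos of seed 7mer, mirna id)

    def _mark(start: int, end: int, site: str) -> None:
        for off, ch in enumerate(site):
            p = (start + off) % L
            if fixed[p]:
                raise FixtureGenerationError("planted sites overlap")
            chars[p] = ch
            fixed[p] = True
        for p in range(start - spec.spacer, end + spec.spacer):
            blocked[p % L] = True

    total_len = sum(
        count * len(mir.residues)
        for mir, (count, _) in zip(mirnas, spec.planted_sites)
    )
    if total_len + spec.spacer * (sum(c for c, _ in spec.planted_sites) + 1) > L:
        raise FixtureGenerationError("planted sites plus spacers exceed circRNA length")

    for mir, (count, one_spanning) in zip(mirnas, spec.planted_sites):
        if count == 0:
            continue
        site = revcomp(mir.residues)
        r = len(site)
        ground[mir.id] = []
        n_body = count - (1 if one_spanning else 0)
        if one_spanning:
            # split so the seed 7-mer (site offsets r-8..r-2) straddles position 0
            a = int(rng.integers(r - 7, r - 1))  # prefix length in [r-7, r-2]
            start = L - a
            _mark(start, start + r, site)
            ground[mir.id].append((start, start + r, True))
            sanctioned.add(((start + r - 8) % L, mir.id))
        for _copy in range(n_body):
            for _attempt in range(2000):
                start = int(rng.integers(0, L - r + 1))
                window = [(p % L) for p in range(start - spec.spacer, start + r + spec.spacer)]
                if not any(blocked[p] for p in window):
                    break
            else:
                raise FixtureGenerationError("could not pack a body site")
            _mark(start, start + r, site)
            ground[mir.id].append((start, start + r, False))
            sanctioned.add((start + r - 8, mir.id))

    free = [p for p in range(L) if chars[p] is None]
    for p in free:
        chars[p] = _BASES[int(rng.integers(0, 4))]

    forbidden = {_seed_7mer(m.residues): m.id for m in mirnas}
    for _round in range(200):
        s = "".join(chars)  # type: ignore[arg-type]
        doubled = s + s[:6]
        dirty: set[int] = set()
        for p in range(L):
            w = doubled[p : p + 7]
            hit = forbidden.get(w)
            if hit is not None and (p, hit) not in sanctioned:
                positions = [(p + off) % L for off in range(7) if not fixed[(p + off) % L]]
                if not positions:
                    raise FixtureGenerationError(
                        "stray seed match lies entirely inside planted residues"
                    )
                dirty.update(positions)
        if not dirty:
            break
        for p in sorted(dirty):
            chars[p] = _BASES[int(rng.integers(0, 4))]
    else:
        raise FixtureGenerationError("background rejection sampling did not converge")

    circ = NucleotideSequence(
        id=f"synthetic-circ-{spec.seed}", residues="".join(chars), topology="circular"
    )
    return circ, ground


def make_target_table(spec: FixtureSpec) -> list[TargetInteraction]:
    """Co-targeting block plus sparse background interactions.

    Every block gene is targeted by every block miRNA; all other
    (miRNA, gene) pairs — bound or not — are included independently with
    probability ``sparse_rate``.
    """
    rng = np.random.default_rng([spec.seed, 17])
    block_genes = set(spec.block_gene_ids)
    block_mirnas = set(spec.block_mirna_ids)
    interactions: list[TargetInteraction] = []
    for gene in spec.block_gene_ids:
        for mid in spec.block_mirna_ids:
            interactions.append(TargetInteraction(mid, gene, "Functional MTI"))
    draws = rng.random((spec.n_mirnas, spec.n_genes))
    weak = rng.random((spec.n_mirnas, spec.n_genes)) < 0.5
    for i, mid in enumerate(spec.mirna_ids):
        for j, gene in enumerate(spec.gene_ids):
            if mid in block_mirnas and gene in block_genes:
                continue
            if draws[i, j] < spec.sparse_rate:
                evidence = "Functional MTI (Weak)" if weak[i, j] else "Functional MTI"
                interactions.append(TargetInteraction(mid, gene, evidence))
    return interactions


def make_gene_sets(spec: FixtureSpec) -> GeneSetCollection:
    """Pathways drawn from the gene pool, with a module planted in the block.

    The planted co-regulated module spans ``n_planted_pathways``
    overlapping pathways sampled from the co-target block — a gene list
    containing the block should light up several pathways at once, as a
    genuine convergence signal does, clearing the ~q false-positive floor
    that a single enriched pathway cannot.
    """
    rng = np.random.default_rng([spec.seed, 19])
    genes = np.array(spec.gene_ids, dtype=object)
    block = np.array(spec.block_gene_ids, dtype=object)
    sets = []
    for i in range(1, spec.n_planted_pathways + 1):
        members = tuple(
            sorted(rng.choice(block, size=spec.planted_pathway_size, replace=False))
        )
        sets.append(
            GeneSet(id=f"PW{i:02d}", name=f"planted_coregulated_{i}", genes=members)
        )
    for i in range(spec.n_planted_pathways + 1, spec.n_pathways + 1):
        members = tuple(sorted(rng.choice(genes, size=spec.pathway_size, replace=False)))
        sets.append(GeneSet(id=f"PW{i:02d}", name=f"random_pathway_{i}", genes=members))
    return GeneSetCollection(tuple(sets))


@dataclass(frozen=True)
class FixtureBundle:
    """Everything one standard synthetic run needs, plus the ground truth."""

    spec: FixtureSpec
    mirnas: tuple[NucleotideSequence, ...]
    circ: NucleotideSequence
    ground_truth: dict[str, list[tuple[int, int, bool]]]
    interactions: tuple[TargetInteraction, ...]
    gene_sets: GeneSetCollection


def make_standard_fixture(seed: int = 0, spec: FixtureSpec | None = None) -> FixtureBundle:
    spec = spec if spec is not None else FixtureSpec(seed=seed)
    mirnas = make_mirnas(spec)
    circ, ground = make_sponge_circ(spec, mirnas)
    interactions = make_target_table(spec)
    gene_sets = make_gene_sets(spec)
    return FixtureBundle(
        spec=spec,
        mirnas=tuple(mirnas),
        circ=circ,
        ground_truth=ground,
        interactions=tuple(interactions),
        gene_sets=gene_sets,
    )


def write_fixture_files(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit the fixture as standard FASTA/TSV/GMT files (CLI-ready)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "circ": outdir / "circ.fasta",
        "mirnas": outdir / "mirnas.fasta",
        "targets": outdir / "targets.tsv",
        "genesets": outdir / "genesets.gmt",
    }
    write_fasta([bundle.circ], paths["circ"])
    write_fasta(bundle.mirnas, paths["mirnas"])
    write_target_table(bundle.interactions, paths["targets"])
    write_gene_sets(bundle.gene_sets, paths["genesets"])
    return paths


def make_enrichment_testbed(
    seed: int,
    n_strong: int = 30,
    n_borderline: int = 400,
    pathway_size: int = 12,
    pool_ramp: tuple[int, int] = (3, 10),
    n_extra_pool: int = 90,
    n_genes: int = 12000,
) -> tuple[GeneSetCollection, list[str]]:
    """Disjoint pathways whose pool membership ramps from weak to strong.

    For calibration checks the null distribution of the enriched-pathway
    count must be spread out, not parked at zero.  This testbed uses
    mutually disjoint pathways inside a large explicit universe:
    ``n_strong`` pathways lie entirely inside the sampling pool (always
    enriched in any sizeable pool draw, anchoring the BH threshold) and
    ``n_borderline`` pathways contribute a pool-member count ramping
    linearly over ``pool_ramp``, so each is enriched in some draws but
    not others, nearly independently of the rest.  The resulting count
    varies over tens of values and the permutation p of a null draw is
    close to uniform.
    """
    rng = np.random.default_rng([seed, 23])
    n_pathways = n_strong + n_borderline
    lo, hi = pool_ramp
    in_pool_counts = [pathway_size] * n_strong + [
        int(round(lo + (hi - lo) * i / max(n_borderline - 1, 1)))
        for i in range(n_borderline)
    ]
    n_pool = sum(in_pool_counts) + n_extra_pool
    n_outside_members = n_pathways * pathway_size - sum(in_pool_counts)
    if n_pool + n_outside_members > n_genes:
        raise ValueError("n_genes too small for the requested testbed")
    genes = [f"BG{i:05d}" for i in range(1, n_genes + 1)]
    order = rng.permutation(n_genes)
    pool_idx = order[:n_pool]
    outside_idx = order[n_pool : n_pool + n_outside_members]
    pool = sorted(genes[i] for i in pool_idx)
    sets = []
    p_pos = 0
    o_pos = 0
    for i, k_in in enumerate(in_pool_counts):
        members = [genes[j] for j in pool_idx[p_pos : p_pos + k_in]]
        p_pos += k_in
        k_out = pathway_size - k_in
        members += [genes[j] for j in outside_idx[o_pos : o_pos + k_out]]
        o_pos += k_out
        sets.append(
            GeneSet(id=f"TB{i + 1:03d}", name=f"testbed_{i + 1}", genes=tuple(sorted(members)))
        )
    collection = GeneSetCollection(tuple(sets), frozenset(genes))
    return collection, pool
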