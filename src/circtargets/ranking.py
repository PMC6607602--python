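"""Common-target scoring: rank genes by how often circRNA-bound miRNAs hit them.

The per-gene statistic is the common targeting time

    CT_g = sum over circRNA-bound miRNAs targeting g of nbs(miRNA),

where nbs is the number of binding sites that miRNA has on the circRNA.
Genes targeted by many bound miRNAs (or by miRNAs with many sites)
accumulate a high CT and are the prioritized sponge-target candidates.
The module also builds the comparison gene lists ranked by alignment
score or duplex energy, and small descriptive summaries (CT histogram,
site density).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

from .io_formats import TargetInteraction
from .scanner import MiRNASiteSummary

Metric = Literal["ct", "pairing_score", "binding_energy"]


@dataclass(frozen=True)
class CTRecord:
    """One gene with its common targeting time and contributing miRNAs."""

    gene: str
    ct: int
    contributors: tuple[tuple[str, int], ...]  # (mirna_id, nbs)

    def __post_init__(self) -> None:
        if not self.contributors:
            raise ValueError(f"CTRecord {self.gene!r} has no contributors")
        if self.ct != sum(n for _, n in self.contributors):
            raise ValueError(f"CTRecord {self.gene!r}: ct != sum of contributor nbs")


@dataclass(frozen=True)
class MetricGeneList:
    metric: Metric
    fraction: float
    mirnas: tuple[str, ...]
    genes: tuple[str, ...]


def compute_ct(
    summaries: Sequence[MiRNASiteSummary],
    interactions: Sequence[TargetInteraction],
) -> list[CTRecord]:
    """Sum nbs over bound miRNAs per target gene.

    miRNAs in the interaction table without a binding site contribute
    nothing; genes reached by no bound miRNA are absent from the result.
    Records are returned sorted by gene symbol.
    """
    if not summaries:
        raise ValueError("compute_ct requires at least one bound miRNA")
    nbs = {s.mirna_id: s.nbs for s in summaries}
    per_gene: dict[str, dict[str, int]] = {}
    for it in interactions:
        n = nbs.get(it.mirna_id)
        if n is None:
            continue
        per_gene.setdefault(it.gene, {})[it.mirna_id] = n
    records = []
    for gene in sorted(per_gene):
        contribs = tuple(sorted(per_gene[gene].items()))
        records.append(
            CTRecord(gene=gene, ct=sum(n for _, n in contribs), contributors=contribs)
        )
    return records


def rank_and_select(records: Sequence[CTRecord], top_n: int = 100) -> list[CTRecord]:
    """Sort by CT descending (ties by gene symbol ascending), keep top_n."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    ordered = sorted(records, key=lambda r: (-r.ct, r.gene))
    return ordered[:top_n]


def ct_distribution(records: Sequence[CTRecord]) -> dict[int, int]:
    """Histogram {ct value -> number of genes}; counts sum to len(records)."""
    return dict(sorted(Counter(r.ct for r in records).items()))


def metric_gene_list(
    summaries: Sequence[MiRNASiteSummary],
    interactions: Sequence[TargetInteraction],
    metric: Metric,
    fraction: float = 0.10,
) -> MetricGeneList:
    """Union of targets of the top-``fraction`` miRNAs by score or energy.

    miRNAs are ranked by best alignment score descending
    (``pairing_score``) or best duplex energy ascending
    (``binding_energy``); ties by miRNA id.  ``ceil(fraction * count)``
    miRNAs are selected, so any positive fraction selects at least one.
    """
    if metric not in ("pairing_score", "binding_energy"):
        raise ValueError(f"metric must be pairing_score or binding_energy, got {metric!r}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not summaries:
        raise ValueError("metric_gene_list requires at least one bound miRNA")
    if metric == "pairing_score":
        keyed = sorted(summaries, key=lambda s: (-s.best_score, s.mirna_id))
    else:
        keyed = sorted(summaries, key=lambda s: (s.best_energy, s.mirna_id))
    n_sel = math.ceil(fraction * len(keyed))
    selected = tuple(s.mirna_id for s in keyed[:n_sel])
    sel_set = set(selected)
    genes = tuple(sorted({it.gene for it in interactions if it.mirna_id in sel_set}))
    return MetricGeneList(metric=metric, fraction=fraction, mirnas=selected, genes=genes)


def site_density(summaries: Sequence[MiRNASiteSummary], L: int) -> float:
    """Binding sites per kilobase of circRNA: (sum of nbs) * 1000 / L."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return sum(s.nbs for s in summaries) * 1000.0 / L
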