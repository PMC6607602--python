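"""End-to-end orchestration: read -> junction -> scan -> CT -> enrichment.

The pipeline is deterministic: every random draw (the permutation null)
descends from ``RunConfig.seed``, and identical configs plus inputs give
byte-identical output files.  Multi-record circRNA FASTA input runs the
pipeline independently per record with per-record output prefixes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import enrichment as enr
from . import io_formats as io
from . import ranking
from .scanner import ScannerParams, scan_circ

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    circ_fasta: str | Path = ""
    mirna_fasta: str | Path = ""
    targets_tsv: str | Path = ""
    genesets_gmt: str | Path | None = None
    out_prefix: str | Path = "run"
    flank: int = 30
    scanner: ScannerParams = field(default_factory=ScannerParams)
    top_n: int = 100
    metric: str = "ct"
    fraction: float = 0.10
    q_threshold: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    species_regex: str | None = None
    keep_support_types: tuple[str, ...] | None = None


def validate_config(config: RunConfig) -> list[str]:
    """Return every problem with the config (empty list = valid)."""
    problems: list[str] = []
    for name in ("circ_fasta", "mirna_fasta", "targets_tsv"):
        p = getattr(config, name)
        if not p:
            problems.append(f"{name} is required")
        elif not Path(p).exists():
            problems.append(f"{name} does not exist: {p}")
    if config.genesets_gmt is not None and not Path(config.genesets_gmt).exists():
        problems.append(f"genesets_gmt does not exist: {config.genesets_gmt}")
    if config.flank < 1:
        problems.append(f"flank must be >= 1, got {config.flank}")
    if config.top_n < 1:
        problems.append(f"top_n must be >= 1, got {config.top_n}")
    if config.metric not in ("ct", "pairing_score", "binding_energy"):
        problems.append(f"unknown metric {config.metric!r}")
    if not 0 < config.fraction <= 1:
        problems.append(f"fraction must be in (0, 1], got {config.fraction}")
    if not 0 < config.q_threshold <= 1:
        problems.append(f"q_threshold must be in (0, 1], got {config.q_threshold}")
    if config.n_perm < 1:
        problems.append(f"n_perm must be >= 1, got {config.n_perm}")
    if config.species_regex is not None:
        try:
            re.compile(config.species_regex)
        except re.error as exc:
            problems.append(f"species_regex does not compile: {exc}")
    return problems


def _select_gene_list(config, top_records, summaries, interactions) -> list[str]:
    if config.metric == "ct":
        return [r.gene for r in top_records]
    mgl = ranking.metric_gene_list(
        summaries, interactions, config.metric, config.fraction
    )
    return list(mgl.genes)


def run_pipeline(config: RunConfig) -> dict[str, dict]:
    """Run the full analysis; returns a per-circRNA machine-readable summary.

    Stages (fixed order, logged): read inputs, build junction and scan,
    compute and rank CT, select the gene list by the configured metric,
    enrich against the gene sets, run the permutation convergence test,
    write reports.  The enrichment stages are skipped with a notice when
    no gene-set file is configured.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))

    logger.info("stage read: loading inputs")
    circs = io.read_fasta(config.circ_fasta, topology="circular")
    mirnas = io.read_fasta(config.mirna_fasta, topology="linear")
    if config.species_regex is not None:
        rx = re.compile(config.species_regex)
        mirnas = [m for m in mirnas if rx.search(m.id)]
        logger.info("species filter kept %d miRNAs", len(mirnas))
    if not mirnas:
        raise ValueError("no miRNAs left after species filtering")
    interactions = io.read_target_table(
        config.targets_tsv, keep_support_types=config.keep_support_types
    )
    gene_sets = (
        io.read_gene_sets(config.genesets_gmt) if config.genesets_gmt else None
    )

    results: dict[str, dict] = {}
    multi = len(circs) > 1
    for idx, circ in enumerate(circs):
        prefix = Path(str(config.out_prefix) + (f".{circ.id}" if multi else ""))
        logger.info("stage scan: %s (%d nt) vs %d miRNAs", circ.id, circ.length, len(mirnas))
        sites, summaries = scan_circ(circ, mirnas, config.scanner, k=config.flank)
        logger.info(
            "stage scan: %d sites, %d bound miRNAs", len(sites), len(summaries)
        )

        summary: dict = {
            "circ_id": circ.id,
            "circ_length": circ.length,
            "n_mirnas_scanned": len(mirnas),
            "n_bound_mirnas": len(summaries),
            "n_sites": len(sites),
            "n_junction_sites": sum(1 for s in sites if s.spans_junction),
            "site_density_per_kb": ranking.site_density(summaries, circ.length),
        }

        if not summaries:
            logger.warning("stage ct: no bound miRNAs for %s; writing empty reports", circ.id)
            io.write_report(
                [], sites, None, prefix, parameters=_param_dict(config), seed=config.seed
            )
            summary.update({"n_genes": 0, "top_genes": []})
            results[circ.id] = summary
            continue

        logger.info("stage ct: computing common targeting times")
        records = ranking.compute_ct(summaries, interactions)
        top = ranking.rank_and_select(records, config.top_n)
        dist = ranking.ct_distribution(records)
        summary.update(
            {
                "n_genes": len(records),
                "max_ct": max(r.ct for r in records),
                "ct_distribution": {str(k): v for k, v in dist.items()},
                "top_genes": [(r.gene, r.ct) for r in top[:10]],
            }
        )

        gene_list = _select_gene_list(config, top, summaries, interactions)
        rows = None
        perm = None
        if gene_sets is None:
            logger.info("stage enrichment: no gene sets configured, skipping")
        else:
            logger.info("stage enrichment: %d pathways", len(gene_sets))
            rows, enriched = enr.enrich(gene_list, gene_sets, config.q_threshold)
            pool = sorted(
                {
                    it.gene
                    for it in interactions
                    if it.mirna_id in {s.mirna_id for s in summaries}
                }
            )
            list_size = min(len(gene_list), len(pool))
            rng = np.random.default_rng([config.seed, idx])
            perm = enr.permutation_test(
                enriched,
                list_size,
                pool,
                gene_sets,
                q_threshold=config.q_threshold,
                n_perm=config.n_perm,
                seed=rng,
            )
            summary.update(
                {
                    "enriched_pathways": enriched,
                    "target_gene_pool": len(pool),
                    "permutation_empirical_p": perm.empirical_p,
                }
            )
            logger.info(
                "stage permutation: observed %d enriched, empirical p = %.4g",
                enriched,
                perm.empirical_p,
            )

        paths = io.write_report(
            ranking.rank_and_select(records, len(records)),  # full ranked list
            sites,
            rows,
            prefix,
            permutation=perm,
            parameters=_param_dict(config),
            seed=config.seed,
        )
        summary["outputs"] = {k: str(v) for k, v in paths.items()}
        results[circ.id] = summary
    return results


def _param_dict(config: RunConfig) -> dict:
    sc = config.scanner
    return {
        "flank": config.flank,
        "top_n": config.top_n,
        "metric": config.metric,
        "fraction": config.fraction,
        "q_threshold": config.q_threshold,
        "n_perm": config.n_perm,
        "score_threshold": sc.score_threshold,
        "energy_threshold": sc.energy_threshold,
        "strict": sc.strict,
    }
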