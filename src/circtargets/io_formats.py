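"""Readers and writers for the external formats the pipeline touches.

Sequences travel as FASTA, miRNA->gene interactions as a two-column TSV
(miRTarBase-style ``miRNA`` / ``Target Gene`` headers), gene sets as GMT,
and results as TSV reports plus one JSON run summary.  All readers validate
strictly — an illegal residue or a malformed line raises instead of being
silently dropped — and all writers are byte-deterministic for fixed inputs.

Coordinate convention: internal coordinates are 0-based half-open; the TSV
reports print 1-based inclusive coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_ALLOWED_INPUT = frozenset("ACGUTacgut")

Topology = Literal["circular", "linear"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A well-formed file carries content that violates an invariant."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A normalized RNA sequence (circRNA or mature miRNA).

    ``residues`` are uppercase over {A, C, G, U}; DNA input is transcribed
    (T -> U) during normalization.  ``topology`` is ``"circular"`` for
    circRNAs, whose coordinates wrap modulo the length, and ``"linear"``
    for miRNAs.
    """

    id: str
    residues: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-normalized residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TargetInteraction:
    """One experimentally supported miRNA -> gene interaction."""

    mirna_id: str
    gene: str
    evidence: str | None = None


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    genes: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetCollection:
    """A GMT-style pathway collection plus the background gene universe.

    The universe defaults to the union of all member genes; callers may
    override it (e.g. with the full target-gene list) at construction.
    """

    sets: tuple[GeneSet, ...]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            object.__setattr__(
                self, "universe", frozenset(g for s in self.sets for g in s.genes)
            )

    def __len__(self) -> int:
        return len(self.sets)


def normalize_sequence(raw: str, record_id: str = "<sequence>") -> str:
    """Uppercase and transcribe (T -> U) a raw sequence string.

    Characters outside {A, C, G, U, T} (case-insensitive), including N and
    gap characters, raise :class:`ValidationError` naming the record and
    the 1-based offending position: losing sites silently is worse than a
    loud error.
    """
    for pos, ch in enumerate(raw, start=1):
        if ch not in _ALLOWED_INPUT:
            raise ValidationError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path, topology: Topology = "linear") -> list[NucleotideSequence]:
    """Read and normalize a FASTA file into :class:`NucleotideSequence` records.

    Record ids are the first whitespace-delimited header token; order is
    preserved.  Empty files and duplicate ids are errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = normalize_sequence(str(rec.seq), rec.id)
        out.append(NucleotideSequence(id=rec.id, residues=residues, topology=topology))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_target_table(
    path: str | Path,
    keep_support_types: Sequence[str] | None = None,
) -> list[TargetInteraction]:
    """Read a miRNA->gene interaction TSV and collapse to unique pairs.

    The header must contain ``miRNA`` and ``Target Gene`` columns; a
    ``Support Type`` column is optional.  Exact duplicate (miRNA, gene)
    pairs are collapsed to one interaction (first evidence kept) and the
    collapse count is logged.  ``keep_support_types``, when given, keeps
    only rows whose ``Support Type`` is in that set before collapsing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("miRNA", "Target Gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if df.empty:
        raise ValidationError(f"{path}: interaction table has no rows")
    has_support = "Support Type" in df.columns
    if keep_support_types is not None:
        if not has_support:
            raise FormatError(
                f"{path}: evidence filter requested but no 'Support Type' column"
            )
        df = df[df["Support Type"].isin(set(keep_support_types))]
        if df.empty:
            raise ValidationError(f"{path}: no rows left after evidence filtering")
    interactions: list[TargetInteraction] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    i_mirna = df.columns.get_loc("miRNA")
    i_gene = df.columns.get_loc("Target Gene")
    i_support = df.columns.get_loc("Support Type") if has_support else None
    for row in df.itertuples(index=False):
        mirna = row[i_mirna].strip()
        gene = row[i_gene].strip()
        if not gene:
            raise ValidationError(f"{path}: empty gene symbol (miRNA {mirna!r})")
        if not mirna:
            raise ValidationError(f"{path}: empty miRNA id (gene {gene!r})")
        key = (mirna, gene)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        evidence = row[i_support] if has_support else None
        interactions.append(TargetInteraction(mirna, gene, evidence or None))
    if n_dup:
        logger.info("collapsed %d duplicate interaction rows in %s", n_dup, path)
    return interactions


def write_target_table(interactions: Iterable[TargetInteraction], path: str | Path) -> None:
    rows = [
        {"miRNA": it.mirna_id, "Target Gene": it.gene, "Support Type": it.evidence or ""}
        for it in interactions
    ]
    pd.DataFrame(rows, columns=["miRNA", "Target Gene", "Support Type"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (``id TAB description TAB gene...`` per line)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            genes = tuple(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
            sets.append(GeneSet(id=fields[0], name=fields[1], genes=genes))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    if universe is not None:
        return GeneSetCollection(tuple(sets), frozenset(universe))
    return GeneSetCollection(tuple(sets))


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.id, s.name, *s.genes]) + "\n")


def write_report(
    ct_records: Sequence,
    sites: Sequence,
    enrichment: Sequence | None,
    path_prefix: str | Path,
    *,
    permutation=None,
    parameters: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the ranked-gene, site, and enrichment TSVs plus a JSON summary.

    ``ct_records`` / ``sites`` / ``enrichment`` are the domain objects from
    :mod:`circtargets.ranking`, :mod:`circtargets.scanner` and
    :mod:`circtargets.enrichment`; they are duck-typed here to keep this
    module dependency-free.  Site coordinates are printed 1-based
    inclusive.  Identical inputs yield byte-identical files.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes_path = prefix.with_name(prefix.name + "_genes.tsv")
    with open(genes_path, "w") as fh:
        fh.write("gene\tct\tcontributors\n")
        for rec in ct_records:
            contrib = ";".join(f"{m}:{n}" for m, n in sorted(rec.contributors))
            fh.write(f"{rec.gene}\t{rec.ct}\t{contrib}\n")
    paths["genes"] = genes_path

    sites_path = prefix.with_name(prefix.name + "_sites.tsv")
    with open(sites_path, "w") as fh:
        fh.write("miRNA\tcirc_id\tstart\tend\tscore\tenergy\tspans_junction\n")
        for s in sites:
            fh.write(
                f"{s.mirna_id}\t{s.circ_id}\t{s.start + 1}\t{s.end}\t"
                f"{s.score:.2f}\t{s.energy:.2f}\t{str(s.spans_junction).lower()}\n"
            )
    paths["sites"] = sites_path

    enr_path = prefix.with_name(prefix.name + "_enrichment.tsv")
    with open(enr_path, "w") as fh:
        fh.write(
            "pathway_id\toverlap\tset_size\tlist_size\tuniverse_size\tp\tq\n"
        )
        for row in enrichment or ():
            fh.write(
                f"{row.pathway_id}\t{row.overlap}\t{row.set_size}\t"
                f"{row.list_size}\t{row.universe_size}\t{row.p:.6g}\t{row.q:.6g}\n"
            )
    paths["enrichment"] = enr_path

    summary: dict = {
        "seed": seed,
        "parameters": dict(parameters or {}),
        "counts": {
            "genes": len(ct_records),
            "sites": len(sites),
            "pathways_tested": len(enrichment) if enrichment is not None else 0,
        },
    }
    if permutation is not None:
        summary["permutation"] = {
            "observed_enriched": permutation.observed_enriched,
            "n_perm": permutation.n_perm,
            "empirical_p": permutation.empirical_p,
        }
    summary_path = prefix.with_name(prefix.name + "_summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = summary_path
    return paths
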