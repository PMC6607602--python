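import pytest

from circtargets.enrichment import enrich
from circtargets.fixtures import (
    FixtureGenerationError,
    FixtureSpec,
    make_enrichment_testbed,
    make_gene_sets,
    make_mirnas,
    make_sponge_circ,
    make_target_table,
    write_fixture_files,
)
from circtargets.io_formats import read_fasta, read_gene_sets, read_target_table
from circtargets.ranking import compute_ct, rank_and_select
from circtargets.scanner import MiRNASiteSummary, scan_circ

from oracles import oracle_ct


class TestMakeMirnas:
    def test_deterministic_for_fixed_seed(self):
        spec = FixtureSpec(seed=4)
        assert make_mirnas(spec) == make_mirnas(spec)

    def test_lengths_within_range(self):
        spec = FixtureSpec(seed=4, mirna_length=(20, 23))
        assert all(20 <= m.length <= 23 for m in make_mirnas(spec))

    def test_no_duplicates_at_scale(self):
        spec = FixtureSpec(seed=4, n_mirnas=100, planted_sites=())
        seqs = [m.residues for m in make_mirnas(spec)]
        assert len(set(seqs)) == 100


class TestMakeSpongeCirc:
    def test_deterministic_for_fixed_seed(self):
        spec = FixtureSpec(seed=5)
        mirnas = make_mirnas(spec)
        c1, g1 = make_sponge_circ(spec, mirnas)
        c2, g2 = make_sponge_circ(spec, mirnas)
        assert c1 == c2 and g1 == g2

    def test_ground_truth_counts_match_spec(self, bundle):
        for (count, spanning), mid in zip(
            bundle.spec.planted_sites, bundle.spec.mirna_ids
        ):
            truth = bundle.ground_truth[mid]
            assert len(truth) == count
            assert sum(1 for *_, sp in truth if sp) == (1 if spanning else 0)

    def test_planted_residues_are_reverse_complements(self, bundle):
        from circtargets.fixtures import revcomp

        L = bundle.circ.length
        doubled = bundle.circ.residues * 2
        by_id = {m.id: m for m in bundle.mirnas}
        for mid, sites in bundle.ground_truth.items():
            for start, end, _ in sites:
                assert doubled[start:end] == revcomp(by_id[mid].residues)

    def test_infeasible_packing_raises(self):
        spec = FixtureSpec(seed=5, circ_length=100)
        with pytest.raises(FixtureGenerationError):
            make_sponge_circ(spec, make_mirnas(spec))

    def test_background_free_of_strict_hits(self):
        spec = FixtureSpec(seed=6, planted_sites=(), circ_length=600)
        mirnas = make_mirnas(spec)
        circ, _ = make_sponge_circ(spec, mirnas)
        sites, summaries = scan_circ(circ, mirnas)
        assert sites == [] and summaries == []


class TestMakeTargetTable:
    def test_block_genes_get_full_block_ct(self):
        spec = FixtureSpec(seed=7)
        interactions = make_target_table(spec)
        summaries = [
            MiRNASiteSummary(mid, 1, 200.0, -20.0) for mid in spec.bound_mirna_ids
        ]
        ct = {r.gene: r.ct for r in compute_ct(summaries, interactions)}
        # with all nbs = 1 every block gene counts its >= block_mirnas targeting miRNAs
        for gene in spec.block_gene_ids:
            assert ct[gene] >= spec.block_mirnas

    def test_ct_profile_matches_design_matrix_oracle(self):
        spec = FixtureSpec(seed=7)
        interactions = make_target_table(spec)
        summaries = [
            MiRNASiteSummary(mid, int(i % 3 + 1), 200.0, -20.0)
            for i, mid in enumerate(spec.bound_mirna_ids)
        ]
        got = {r.gene: r.ct for r in compute_ct(summaries, interactions)}
        assert got == oracle_ct(summaries, interactions)

    def test_reproducible(self):
        spec = FixtureSpec(seed=8)
        assert make_target_table(spec) == make_target_table(spec)


class TestMakeGeneSets:
    def test_planted_pathways_inside_block(self):
        spec = FixtureSpec(seed=9)
        coll = make_gene_sets(spec)
        block = set(spec.block_gene_ids)
        planted = [s for s in coll.sets if s.name.startswith("planted")]
        assert len(planted) == spec.n_planted_pathways
        for s in planted:
            assert set(s.genes) <= block

    def test_gmt_bytes_reproducible(self, tmp_path):
        spec = FixtureSpec(seed=9)
        from circtargets.io_formats import write_gene_sets

        a, b = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gene_sets(make_gene_sets(spec), a)
        write_gene_sets(make_gene_sets(spec), b)
        assert a.read_bytes() == b.read_bytes()

    def test_top_ct_list_flags_planted_pathways_first(self, bundle):
        sites, summaries = scan_circ(bundle.circ, bundle.mirnas)
        records = compute_ct(summaries, list(bundle.interactions))
        top = rank_and_select(records, 50)
        rows, count = enrich([r.gene for r in top], bundle.gene_sets)
        planted_ids = {
            s.id for s in bundle.gene_sets.sets if s.name.startswith("planted")
        }
        assert {r.pathway_id for r in rows[: len(planted_ids)]} == planted_ids
        assert count >= len(planted_ids)


class TestFixtureFiles:
    def test_files_roundtrip_through_readers(self, bundle, tmp_path):
        paths = write_fixture_files(bundle, tmp_path)
        assert read_fasta(paths["circ"], topology="circular")[0] == bundle.circ
        assert tuple(read_fasta(paths["mirnas"])) == bundle.mirnas
        got = read_target_table(paths["targets"])
        assert {(i.mirna_id, i.gene) for i in got} == {
            (i.mirna_id, i.gene) for i in bundle.interactions
        }
        coll = read_gene_sets(paths["genesets"])
        assert {s.id: s.genes for s in coll.sets} == {
            s.id: s.genes for s in bundle.gene_sets.sets
        }


class TestEnrichmentTestbed:
    def test_pool_and_sets_reproducible(self):
        a_sets, a_pool = make_enrichment_testbed(seed=3)
        b_sets, b_pool = make_enrichment_testbed(seed=3)
        assert a_pool == b_pool
        assert a_sets.sets == b_sets.sets

    def test_pathways_disjoint(self):
        sets, _ = make_enrichment_testbed(seed=3)
        seen = set()
        for s in sets.sets:
            assert not (set(s.genes) & seen)
            seen.update(s.genes)

    def test_strong_pathways_lie_inside_pool(self):
        sets, pool = make_enrichment_testbed(seed=3, n_strong=10, n_borderline=20)
        pool_set = set(pool)
        for s in sets.sets[:10]:
            assert set(s.genes) <= pool_set
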