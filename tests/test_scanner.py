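import pytest

from circtargets.fixtures import FixtureSpec, make_mirnas, make_sponge_circ, revcomp
from circtargets.io_formats import NucleotideSequence
from circtargets.scanner import (
    ScannerParams,
    duplex_energy,
    parse_external_scanner_output,
    scan_circ,
    scan_pair,
)

from conftest import rand_rna
from oracles import oracle_column_energy, oracle_scan


def _mir(rng, n=22, mid="m1"):
    return NucleotideSequence(mid, rand_rna(rng, n))


class TestScanPair:
    def test_planted_perfect_site_recovered_exactly(self, rng):
        mir = _mir(rng)
        tgt = rand_rna(rng, 20) + revcomp(mir.residues) + rand_rna(rng, 18)
        sites = scan_pair(mir, tgt)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end) == (20, 42)
        assert set(s.alignment[1]) == {"|"}  # all Watson-Crick
        assert s.score == 15 * 5 + 7 * 5 * 4  # body + scaled seed
        assert s.seed_strict

    def test_seed_mismatch_killed_by_strict_mode(self, rng):
        mir = _mir(rng)
        site = list(revcomp(mir.residues))
        # break the pair of miRNA position 5: target offset m-1-4
        pos = len(site) - 5
        site[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[site[pos]]
        tgt = rand_rna(rng, 20) + "".join(site) + rand_rna(rng, 18)
        assert scan_pair(mir, tgt, ScannerParams(strict=True)) == []

    def test_no_complementarity_means_no_sites(self):
        mir = NucleotideSequence("polyA", "A" * 22)
        assert scan_pair(mir, "A" * 60) == []

    def test_short_mirna_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            scan_pair(_mir(rng, 8), "ACGU" * 10)

    def test_matches_exhaustive_oracle_on_mixed_targets(self, rng):
        for trial in range(12):
            mir = _mir(rng, int(rng.integers(20, 24)), f"m{trial}")
            if trial % 3 == 0:
                tgt = rand_rna(rng, int(rng.integers(30, 61)))
                params = ScannerParams()
            elif trial % 3 == 1:
                tgt = rand_rna(rng, 12) + revcomp(mir.residues) + rand_rna(rng, 10)
                params = ScannerParams()
            else:
                tgt = (rand_rna(rng, 8) + revcomp(mir.residues) + rand_rna(rng, 10))[:60]
                params = ScannerParams(score_threshold=60.0, strict=False)
            got = [(s.start, s.end, s.score, s.energy, s.alignment) for s in scan_pair(mir, tgt, params)]
            exp = [s[:5] for s in oracle_scan(mir, tgt, params)]
            assert got == exp

    def test_strict_output_is_subset_of_nonstrict(self, rng):
        for trial in range(10):
            mir = _mir(rng, 21, f"m{trial}")
            tgt = rand_rna(rng, 10) + revcomp(mir.residues) + rand_rna(rng, 12)
            strict = scan_pair(mir, tgt, ScannerParams(score_threshold=80.0, strict=True))
            loose = scan_pair(mir, tgt, ScannerParams(score_threshold=80.0, strict=False))
            assert {(s.start, s.end) for s in strict} <= {(s.start, s.end) for s in loose}


class TestDuplexEnergy:
    def test_ten_gc_pairs(self):
        aln = ("G" * 10, "|" * 10, "C" * 10)
        assert duplex_energy(aln) == -30.0

    def test_empty_alignment(self):
        assert duplex_energy(("", "", "")) == 0.0

    def test_matches_per_column_oracle(self, rng):
        params = ScannerParams()
        chars = "ACGU-"
        for _ in range(20):
            n = int(rng.integers(1, 30))
            top = "".join(chars[i] for i in rng.integers(0, 5, n))
            bot = "".join(chars[i] for i in rng.integers(0, 5, n))
            aln = (top, " " * n, bot)
            expected = sum(oracle_column_energy(a, b, params) for a, b in zip(top, bot))
            assert duplex_energy(aln, params) == expected

    def test_malformed_alignment_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy(("AC", "|", "ACG"))


class TestScanCirc:
    def test_recovers_planted_sites_and_counts(self, bundle, scan_results):
        sites, summaries = scan_results
        truth_nbs = {m: len(v) for m, v in bundle.ground_truth.items()}
        assert {s.mirna_id: s.nbs for s in summaries} == truth_nbs
        rec = {}
        for s in sites:
            rec.setdefault(s.mirna_id, set()).add((s.start, s.end, s.spans_junction))
        truth = {m: set(v) for m, v in bundle.ground_truth.items()}
        assert rec == truth
        assert sum(1 for s in sites if s.spans_junction) == 1

    def test_nbs_conservation(self, scan_results):
        sites, summaries = scan_results
        assert sum(s.nbs for s in summaries) == len(sites)

    def test_same_mirna_sites_disjoint_on_circle(self, bundle, scan_results):
        sites, _ = scan_results
        L = bundle.circ.length
        by_mir = {}
        for s in sites:
            cover = {p % L for p in range(s.start, s.end)}
            for other in by_mir.get(s.mirna_id, []):
                assert not cover & other
            by_mir.setdefault(s.mirna_id, []).append(cover)

    def test_unbound_circ_yields_empty_outputs(self, rng):
        spec = FixtureSpec(seed=9, planted_sites=(), circ_length=400)
        mirnas = make_mirnas(spec)
        circ, truth = make_sponge_circ(spec, mirnas)
        assert truth == {}
        sites, summaries = scan_circ(circ, mirnas)
        assert sites == [] and summaries == []

    def test_rotation_shifts_coordinates(self, bundle):
        r = 17
        L = bundle.circ.length
        rotated = NucleotideSequence(
            "rot", bundle.circ.residues[r:] + bundle.circ.residues[:r], topology="circular"
        )
        sites0, summ0 = scan_circ(bundle.circ, bundle.mirnas)
        sites1, summ1 = scan_circ(rotated, bundle.mirnas)
        assert {s.mirna_id: s.nbs for s in summ0} == {s.mirna_id: s.nbs for s in summ1}
        key0 = {(s.mirna_id, (s.start - r) % L, s.end - s.start) for s in sites0}
        # rotating left by r shifts every circular start by -r mod L
        key1 = {(s.mirna_id, s.start % L, s.end - s.start) for s in sites1}
        assert key0 == key1

    def test_empty_mirna_list_rejected(self, bundle):
        with pytest.raises(ValueError, match="non-empty"):
            scan_circ(bundle.circ, [])


class TestExternalBackend:
    def test_parses_hit_lines_only(self):
        text = "\n".join(
            [
                "# comment",
                ">m1\tcirc1\t152.00\t-18.20\t2 21\t5 27\t20\t75.0%\t80.0%",
                ">>m1\tcirc1\t152.00\t-18.20\t...aggregate...",
                "other noise",
            ]
        )
        hits = parse_external_scanner_output(text)
        assert len(hits) == 1
        h = hits[0]
        assert h["mirna_id"] == "m1" and h["score"] == 152.0
        assert (h["start"], h["end"]) == (4, 27)
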