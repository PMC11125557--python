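from collections import Counter

import numpy as np
import pytest

from sclineage.sites import (
    ReadRecord,
    SelectionThresholds,
    UnsupportedFeatureError,
    call_bulk_reference,
    call_gsnv,
    call_gsnvs,
    pair_with_gsnv,
    read_sam,
    select_candidates,
    select_sites,
    sites_from_json,
    sites_to_json,
    validate_gsnv_in_cells,
    _cell_pileups,
)

TH = SelectionThresholds()


def rec(start, bases, q=0.001, cell=0):
    return ReadRecord(cell, start, bases, (q,) * len(bases))


class TestReadSam:
    def test_coordinates_and_quals(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:1000\n"
            "r1\t0\tref\t100\t60\t2M\t*\t0\t0\tAG\t??\n"
        )
        records = read_sam(sam, cell_id=3)
        assert len(records) == 1
        r = records[0]
        assert r.cell_id == 3
        assert (r.start, r.end) == (99, 101)  # POS is 1-based in SAM
        assert r.base_at(99) == "A" and r.base_at(100) == "G"
        assert r.error_at(99) == pytest.approx(1e-3)  # '?' is Phred 30

    def test_soft_clips_are_excluded(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:1000\n"
            "r1\t0\tref\t100\t60\t1S2M\t*\t0\t0\tCAG\t!??\n"
        )
        r = read_sam(sam)[0]
        assert r.bases == "AG" and r.start == 99

    def test_unsupported_cigar_names_the_op(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:1000\n"
            "r1\t0\tref\t100\t60\t2M1I2M\t*\t0\t0\tAGTCA\t?????\n"
        )
        with pytest.raises(UnsupportedFeatureError, match="'I'"):
            read_sam(sam)


class TestBulkReference:
    def test_unanimous_deep_pileup(self):
        assert call_bulk_reference(Counter(A=12)) == "A"

    def test_depth_threshold(self):
        assert call_bulk_reference(Counter(A=9)) is None

    def test_frequency_threshold(self):
        assert call_bulk_reference(Counter(A=7, C=3)) is None
        assert call_bulk_reference(Counter(A=8, C=2)) == "A"


class TestGsnvCalling:
    def test_balanced_heterozygote(self):
        assert call_gsnv(Counter(A=10, T=10)) == ("A", "T")

    def test_low_alternative_frequency(self):
        assert call_gsnv(Counter(A=19, T=1)) is None

    def test_low_depth(self):
        assert call_gsnv(Counter(A=4, T=4)) is None

    def test_call_gsnvs_over_reads(self):
        reads = [rec(10, "AT")] * 10 + [rec(10, "CT")] * 10
        out = call_gsnvs(reads)
        assert out == {10: ("A", "C")}  # position 11 is homozygous T


class TestGsnvValidation:
    def test_two_displaying_cells(self):
        counts = {0: Counter(A=5, T=5), 1: Counter(A=5, T=5)}
        assert validate_gsnv_in_cells(counts, ("A", "T"))

    def test_one_displaying_cell_is_not_enough(self):
        counts = {0: Counter(A=5, T=5), 1: Counter(A=10)}
        assert not validate_gsnv_in_cells(counts, ("A", "T"))

    def test_low_minor_fraction(self):
        counts = {i: Counter(A=9, T=1) for i in range(3)}
        assert not validate_gsnv_in_cells(counts, ("A", "T"))


class TestCandidateSelection:
    def pileups(self, per_cell_bases):
        reads = [
            [rec(50, b, cell=c) for b in bases]
            for c, bases in enumerate(per_cell_bases)
        ]
        return _cell_pileups(reads)

    def test_three_alternative_cells_kept(self):
        piles = self.pileups([["G", "A"]] * 3 + [["A", "A"]] * 7)
        out = select_candidates(piles, {50: "A"}, 10)
        assert out == {50: "G"}

    def test_single_alternative_cell_rejected(self):
        piles = self.pileups([["G", "G"]] + [["A", "A"]] * 9)
        assert select_candidates(piles, {50: "A"}, 10) == {}

    def test_all_cells_alternative_rejected(self):
        piles = self.pileups([["G", "G"]] * 10)
        assert select_candidates(piles, {50: "A"}, 10) == {}

    def test_cells_must_agree_on_the_alternative(self):
        piles = self.pileups([["G", "G"], ["T", "T"], ["C", "C"]] + [["A", "A"]] * 7)
        assert select_candidates(piles, {50: "A"}, 10) == {}


class TestPairing:
    def make_reads(self, candidate=11, gsnvs=(8, 14)):
        # reads co-covering candidate with each gSNV; two cells display both alleles
        reads = []
        for cell in range(2):
            for g in gsnvs:
                lo = min(candidate, g)
                width = abs(candidate - g) + 1
                for allele in "AT":
                    bases = ["C"] * width
                    bases[g - lo] = allele
                    bases[candidate - lo] = "G"
                    reads.append(rec(lo, "".join(bases), cell=cell))
        return [[r for r in reads if r.cell_id == c] for c in range(2)]

    def test_closest_covered_gsnv_wins(self):
        gsnvs = {8: ("A", "T"), 13: ("A", "T")}
        cell_reads = self.make_reads(gsnvs=(8, 13))
        assert pair_with_gsnv(11, gsnvs, cell_reads) == 13  # distance 2 beats 3

    def test_uncovered_nearest_gsnv_is_skipped(self):
        cell_reads = self.make_reads(gsnvs=(14,))
        gsnvs = {9: ("A", "T"), 14: ("A", "T")}  # 9 is closer but never co-covered
        assert pair_with_gsnv(11, gsnvs, cell_reads) == 14

    def test_failing_final_check_rejects_the_pair(self):
        # co-covering reads only ever show one gSNV allele
        reads = [rec(10, "AG", cell=c) for c in range(4) for _ in range(4)]
        cell_reads = [[r for r in reads if r.cell_id == c] for c in range(4)]
        assert pair_with_gsnv(11, {10: ("A", "T")}, cell_reads) is None


class TestPairingTieBreak:
    def test_equal_distance_prefers_lower_position(self):
        t = TestPairing()
        cell_reads = t.make_reads(gsnvs=(8, 14))
        gsnvs = {8: ("A", "T"), 14: ("A", "T")}
        assert pair_with_gsnv(11, gsnvs, cell_reads) == 8


class TestSelectSites:
    def test_empty_input_gives_empty_output(self):
        assert select_sites([], [[], []]) == []

    @pytest.mark.parametrize("mode", ["hybrid", "paired", "singleton"])
    def test_modes_on_noiseless_data(self, mode, noiseless_dataset):
        ds = noiseless_dataset
        obs = select_sites(ds.bulk_reads, ds.cell_reads, mode=mode)
        assert obs
        if mode == "singleton":
            assert all(o.kind == "singleton" for o in obs)
        else:
            # with phasing frequency 1 every candidate has an adjacent gSNV
            assert all(o.kind == "paired" for o in obs)
        positions = [o.candidate_pos for o in obs]
        assert positions == sorted(positions)

    def test_hybrid_and_singleton_find_same_candidates(self, noiseless_dataset):
        ds = noiseless_dataset
        hybrid = select_sites(ds.bulk_reads, ds.cell_reads, mode="hybrid")
        singleton = select_sites(ds.bulk_reads, ds.cell_reads, mode="singleton")
        assert [o.candidate_pos for o in hybrid] == [o.candidate_pos for o in singleton]

    def test_exact_recovery_on_noiseless_data(self, noiseless_dataset):
        """Every selected candidate is a true mutation locus, and every locus
        whose mutated cells are well represented in the reads is selected."""
        ds = noiseless_dataset
        obs = select_sites(ds.bulk_reads, ds.cell_reads, mode="hybrid")
        selected = {o.candidate_pos for o in obs}
        mutation_loci = set(ds.truth.mutation_map)
        assert selected <= mutation_loci  # no false positives
        C = ds.config.n_cells
        expected = set()
        for locus in mutation_loci:
            supporting = 0
            for cell in range(C):
                alt = {
                    "ACGT"[ds.truth.cell_genomes[cell, hap, locus]] for hap in (0, 1)
                } - {"ACGT"[ds.truth.bulk_genome[0, locus]]}
                if not alt:
                    continue
                covering = [
                    r.bases[locus % 2] for r in ds.cell_reads[cell] if r.covers(locus)
                ]
                if (
                    len(covering) >= TH.min_cell_depth
                    and sum(b in alt for b in covering) / len(covering)
                    >= TH.cell_alt_frac
                ):
                    supporting += 1
            if TH.min_alt_cells <= supporting <= C - 1:
                expected.add(locus)
        assert selected == expected

    def test_order_invariance(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(0)
        shuffled = []
        for reads in ds.cell_reads:
            perm = list(rng.permutation(len(reads)))
            shuffled.append([reads[i] for i in perm])
        a = select_sites(ds.bulk_reads, ds.cell_reads, mode="hybrid")
        b = select_sites(list(reversed(ds.bulk_reads)), shuffled, mode="hybrid")
        assert [(o.kind, o.candidate_pos, o.gsnv_pos, o.bulk) for o in a] == [
            (o.kind, o.candidate_pos, o.gsnv_pos, o.bulk) for o in b
        ]
        for oa, ob in zip(a, b):
            assert oa.coverages == ob.coverages

    def test_thresholds_hold_post_hoc(self, noiseless_dataset):
        ds = noiseless_dataset
        obs = select_sites(ds.bulk_reads, ds.cell_reads, mode="hybrid")
        C = ds.config.n_cells
        for o in obs[:25]:
            assert o.n_cells == C
            if o.kind == "paired":
                # at least one phaseable (co-covering) read exists
                ci, gi = o.candidate_index, 1 - o.candidate_index
                assert any(
                    "." not in r.bases for reads in o.cell_reads for r in reads
                )
            covered = sum(l > 0 for l in o.coverages)
            assert covered >= TH.min_alt_cells


class TestSitesJson:
    def test_round_trip(self, noiseless_dataset, tmp_path):
        ds = noiseless_dataset
        obs = select_sites(ds.bulk_reads, ds.cell_reads, mode="hybrid")[:5]
        sites_to_json(obs, tmp_path / "sites.json")
        back = sites_from_json(tmp_path / "sites.json")
        assert len(back) == len(obs)
        for a, b in zip(obs, back):
            assert (a.kind, a.candidate_pos, a.gsnv_pos, a.bulk) == (
                b.kind,
                b.candidate_pos,
                b.gsnv_pos,
                b.bulk,
            )
            assert a.cell_reads == b.cell_reads
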