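"""Channel classifiers: threshold boundaries and brute-force oracles."""

import numpy as np
import pytest

from grcfinder.io import AlignmentRecord, CoverageTrack, GenomicInterval, ReadRecord
from grcfinder.identify import (
    BarcodeSelection,
    VariantCall,
    call_variants_pileup,
    expand_barcodes,
    filter_kmers_against_soma,
    germline_specific_regions,
    germline_specific_snps,
    match_kmers,
    reads_overlapping,
    repeat_reads,
    snp_to_kmers,
)
from grcfinder.seqs import random_sequence, revcomp


def brute_force_regions(testis, kidney, min_len):
    """Per-base scan for maximal testis-covered, kidney-free runs."""
    out = []
    start = None
    for i in range(len(testis) + 1):
        ok = i < len(testis) and testis[i] >= 1 and kidney[i] == 0
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_len:
                out.append((start, i))
            start = None
    return out


def _track(scaffold, depths, tissue=""):
    return CoverageTrack(scaffold, np.asarray(depths), tissue=tissue)


def _aln(read_id, scaffold, start, end, matches=None, strand="+"):
    block = end - start
    return AlignmentRecord(
        read_id, 0, block, GenomicInterval(scaffold, start, end, strand),
        matches=matches if matches is not None else block, block_len=block,
    )


class TestGermlineSpecificRegions:
    def test_minimum_length_boundary(self):
        testis = np.zeros(1000, dtype=int)
        testis[:600] = 1
        regions = germline_specific_regions(_track("s", testis), _track("s", np.zeros(1000, dtype=int)))
        assert [(r.start, r.end) for r in regions] == [(0, 600)]
        testis[:600] = 0
        testis[:400] = 1
        assert germline_specific_regions(
            _track("s", testis), _track("s", np.zeros(1000, dtype=int))
        ) == []

    def test_single_kidney_base_splits_block(self):
        testis = np.zeros(1500, dtype=int)
        testis[0:1200] = 1
        kidney = np.zeros(1500, dtype=int)
        kidney[300] = 1
        regions = germline_specific_regions(_track("s", testis), _track("s", kidney))
        # halves of 300 and 899 bp; only the >= 500 bp half survives
        assert [(r.start, r.end) for r in regions] == [(301, 1200)]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            germline_specific_regions(
                _track("s", np.zeros(10, dtype=int)), _track("s", np.zeros(9, dtype=int))
            )

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = 5_000
            # blocky random coverage so both empty and dense stretches occur
            testis = np.repeat(rng.integers(0, 3, size=n // 50), 50)
            kidney = np.repeat(rng.integers(0, 2, size=n // 100), 100)
            got = germline_specific_regions(
                _track("s", testis), _track("s", kidney), min_len=120
            )
            assert [(r.start, r.end) for r in got] == brute_force_regions(
                testis, kidney, 120
            )


class TestReadsOverlapping:
    REGIONS = [GenomicInterval("s", 500, 1100)]

    def _pair(self, barcode, start, end):
        read = ReadRecord("r", "A" * (end - start), barcode=barcode)
        return (read, _aln("r", "s", start, end))

    def test_overlap_selects(self):
        sel = reads_overlapping(self.REGIONS, [self._pair("B1", 490, 640)])
        assert sel.barcodes == {"B1"}
        assert sel.provenance["B1"] == {"region"}

    def test_ten_bp_boundary(self):
        # overlap exactly 10 -> selected; 9 -> not
        assert reads_overlapping(self.REGIONS, [self._pair("B1", 400, 510)]).barcodes == {"B1"}
        assert reads_overlapping(self.REGIONS, [self._pair("B1", 400, 509)]).barcodes == set()

    def test_barcodeless_read_contributes_nothing(self):
        sel = reads_overlapping(self.REGIONS, [self._pair(None, 490, 640)])
        assert sel.barcodes == set()


def _pairs(reference, placements, sample_reads):
    """Build (read, alignment) pairs from (scaffold, start, sequence) triples."""
    out = []
    for i, (scaf, start, seq) in enumerate(placements):
        read = ReadRecord(f"{sample_reads}.{i}", seq)
        out.append((read, _aln(read.read_id, scaf, start, start + len(seq))))
    return out


class TestPileupCaller:
    REF = {"c": "ACGTACGTACGTACGTACGT"}

    def test_supported_site_called(self):
        # 5 alt reads + 5 ref reads over position 5 (ref C -> alt T)
        alt_seq = "ACGTATGTACGTACGTACGT"
        placements = [("c", 0, alt_seq)] * 5 + [("c", 0, self.REF["c"])] * 5
        calls = call_variants_pileup(
            {("T1", "testis"): _pairs(self.REF, placements, "t")}, self.REF
        )
        assert len(calls) == 1
        call = calls[0]
        assert (call.scaffold, call.position, call.ref_allele, call.alt_allele) == ("c", 5, "C", "T")
        assert call.support[("T1", "testis")] == (5, 10)

    def test_single_alt_read_below_threshold(self):
        alt_seq = "ACGTATGTACGTACGTACGT"
        placements = [("c", 0, alt_seq)] + [("c", 0, self.REF["c"])] * 5
        calls = call_variants_pileup(
            {("T1", "testis"): _pairs(self.REF, placements, "t")}, self.REF
        )
        assert calls == []

    def test_all_reference_not_called(self):
        placements = [("c", 0, self.REF["c"])] * 6
        calls = call_variants_pileup(
            {("T1", "testis"): _pairs(self.REF, placements, "t")}, self.REF
        )
        assert calls == []

    def test_reference_n_site_skipped(self):
        ref = {"c": "ACGTANGTACGT"}
        alt = "ACGTACGTACGT"
        placements = [("c", 0, alt)] * 3
        calls = call_variants_pileup(
            {("T1", "testis"): _pairs(ref, placements, "t")}, ref
        )
        assert calls == []

    def test_minus_strand_reads_counted_after_orienting(self):
        alt_seq = "ACGTATGTACGTACGTACGT"
        pairs = []
        for i in range(3):
            read = ReadRecord(f"m{i}", revcomp(alt_seq))
            pairs.append((read, _aln(read.read_id, "c", 0, 20, strand="-")))
        calls = call_variants_pileup({("T1", "testis"): pairs}, self.REF)
        assert len(calls) == 1 and calls[0].position == 5

    def test_agrees_with_brute_force_pileup_on_random_data(self):
        rng = np.random.default_rng(9)
        ref = {"c": random_sequence(rng, 400)}
        pairs = []
        for i in range(120):
            start = int(rng.integers(0, 350))
            frag = list(ref["c"][start : start + 50])
            if rng.random() < 0.5:
                pos = int(rng.integers(0, 50))
                frag[pos] = "ACGT"[("ACGT".index(frag[pos]) + 1) % 4]
            read = ReadRecord(f"r{i}", "".join(frag))
            pairs.append((read, _aln(read.read_id, "c", start, start + 50)))
        calls = call_variants_pileup({("T1", "testis"): pairs}, ref)
        # oracle: naive per-base tally
        counts: dict[tuple[int, str], int] = {}
        for read, aln in pairs:
            for off, base in enumerate(read.sequence):
                p = aln.target.start + off
                if base != ref["c"][p]:
                    counts[(p, base)] = counts.get((p, base), 0) + 1
        expected_sites = {p for (p, b), n in counts.items() if n >= 2}
        assert {c.position for c in calls} == expected_sites


class TestGermlineSpecificSnps:
    def _call(self, testis_counts, kidney_counts):
        support = {}
        for i, n in enumerate(testis_counts):
            support[(f"T{i+1}", "testis")] = (n, 10)
        for i, n in enumerate(kidney_counts):
            support[(f"K{i+1}", "kidney")] = (n, 10)
        return VariantCall("c", 5, "A", "G", support)

    def test_all_testis_no_kidney_kept(self):
        calls = germline_specific_snps([self._call([3, 4, 2], [0, 0, 0])])
        assert len(calls) == 1

    def test_missing_one_testis_sample_dropped(self):
        assert germline_specific_snps([self._call([3, 4, 0], [0, 0, 0])]) == []
        assert germline_specific_snps([self._call([3, 4, 1], [0, 0, 0])]) == []

    def test_any_kidney_support_dropped(self):
        assert germline_specific_snps([self._call([3, 4, 2], [1, 0, 0])]) == []


class TestSnpToKmers:
    REF = {"c": random_sequence(np.random.default_rng(5), 300)}

    def _call(self, pos):
        ref_base = self.REF["c"][pos]
        alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        return VariantCall("c", pos, ref_base, alt)

    def test_interior_site_yields_k_kmers(self):
        call = self._call(100)
        kmers = snp_to_kmers(call, self.REF, k=29)
        assert len(kmers) == 29
        mutated = self.REF["c"][:100] + call.alt_allele + self.REF["c"][101:]
        for kmer in kmers:
            assert kmer in mutated

    def test_near_start_yields_fewer(self):
        assert len(snp_to_kmers(self._call(10), self.REF, k=29)) == 11

    @pytest.mark.parametrize("pos", [0, 5, 28, 100, 271, 285, 299])
    def test_count_formula(self, pos):
        L = len(self.REF["c"])
        expected = min(29, pos + 1, L - pos)
        assert len(snp_to_kmers(self._call(pos), self.REF, k=29)) == expected

    def test_each_kmer_differs_from_reference_by_the_alt_base(self):
        call = self._call(150)
        for kmer in snp_to_kmers(call, self.REF, k=29):
            # the same window of the unmutated reference differs at one base
            idx = (self.REF["c"][:150] + call.alt_allele + self.REF["c"][151:]).find(kmer)
            ref_window = self.REF["c"][idx : idx + 29]
            diff = [i for i in range(29) if kmer[i] != ref_window[i]]
            assert len(diff) == 1 and idx + diff[0] == 150


class TestKmerFiltering:
    def test_verbatim_presence_removes(self):
        kmers = {"ACGTACGTAC"}
        reads = [ReadRecord("r", "TTTACGTACGTACTTT")]
        assert filter_kmers_against_soma(kmers, reads) == set()

    def test_reverse_complement_presence_removes(self):
        kmers = {"ACGTACGTAC"}
        reads = [ReadRecord("r", "TTT" + revcomp("ACGTACGTAC") + "TTT")]
        assert filter_kmers_against_soma(kmers, reads) == set()

    def test_absent_kmer_kept(self):
        kmers = {"ACGTACGTAC"}
        reads = [ReadRecord("r", "G" * 30)]
        assert filter_kmers_against_soma(kmers, reads) == kmers

    def test_match_kmers_both_strands(self):
        kmers = {"ACGTACGTAC"}
        reads = [
            ReadRecord("r1", "TTACGTACGTACTT", barcode="B1"),
            ReadRecord("r2", "TT" + revcomp("ACGTACGTAC") + "TT", barcode="B2"),
            ReadRecord("r3", "G" * 20, barcode="B3"),
            ReadRecord("r4", "TTACGTACGTACTT", barcode=None),
        ]
        sel = match_kmers(kmers, reads)
        assert sel.barcodes == {"B1", "B2"}
        assert all(sel.provenance[b] == {"snp_kmer"} for b in sel.barcodes)


class TestRepeatReads:
    def _pair(self, barcode, block, identity):
        matches = int(round(block * identity))
        read = ReadRecord("r", "A" * block, barcode=barcode)
        return (read, AlignmentRecord("r", 0, block,
                                      GenomicInterval("rep", 0, block),
                                      matches=matches, block_len=block))

    def test_long_high_identity_selected(self):
        sel = repeat_reads("ACGT" * 50, [self._pair("B1", 120, 0.95)])
        assert sel.barcodes == {"B1"}

    def test_low_identity_rejected(self):
        assert repeat_reads("ACGT" * 50, [self._pair("B1", 120, 0.85)]).barcodes == set()

    def test_short_block_rejected_even_at_full_identity(self):
        assert repeat_reads("ACGT" * 50, [self._pair("B1", 90, 1.0)]).barcodes == set()

    def test_identity_threshold_is_strict(self):
        assert repeat_reads("ACGT" * 50, [self._pair("B1", 100, 0.90)]).barcodes == set()

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError, match="empty repeat"):
            repeat_reads("", [])


class TestExpandBarcodes:
    READS = [
        ReadRecord("r1", "ACGT", barcode="A"),
        ReadRecord("r2", "ACGT", barcode="A"),
        ReadRecord("r3", "ACGT", barcode="B"),
        ReadRecord("r4", "ACGT", barcode=None),
    ]

    def _sel(self, *barcodes):
        sel = BarcodeSelection()
        for b in barcodes:
            sel.add(b, "region")
        return sel

    def test_selected_barcode_recruits_its_reads(self):
        got = expand_barcodes(self._sel("A"), self.READS)
        assert [r.read_id for r in got] == ["r1", "r2"]

    def test_empty_selection_empty_result(self):
        assert expand_barcodes(self._sel(), self.READS) == []

    def test_all_barcodes_recruit_all_barcoded_reads(self):
        got = expand_barcodes(self._sel("A", "B"), self.READS)
        assert [r.read_id for r in got] == ["r1", "r2", "r3"]
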