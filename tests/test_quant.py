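"""Read preprocessing, locus allotment, window classification, RPMR."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from morna import (
    AlignedSegment,
    Category,
    GenomicInterval,
    LocusAssignment,
    QuantParams,
    allot_weights,
    build_locus_index,
    classify,
    derive_regions,
    filter_insert,
    find_candidate_loci,
    normalize_rpmr,
    quantify,
    tabulate,
    trim_adapter,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def seg(start, end, strand="+", read_id="r1", chrom="chr1", n=1):
    return AlignedSegment(read_id, GenomicInterval(chrom, start, end, strand), n)


class TestTrimAndFilter:
    def test_full_adapter_removed(self):
        assert trim_adapter("ACGTACGTACGTAC" + ADAPTER, ADAPTER) == "ACGTACGTACGTAC"

    def test_no_adapter_unchanged(self):
        assert trim_adapter("ACGTACGTACGTACGTAA", ADAPTER) == "ACGTACGTACGTACGTAA"

    def test_terminal_partial_adapter_trimmed(self):
        # oracle: exhaustive scan over all read-suffix / adapter-prefix overlaps
        read = "ACGTACGTACGTAC" + ADAPTER[:8]
        best = None
        for i in range(len(read)):
            k = len(read) - i
            if k >= 6 and read[i:] == ADAPTER[:k]:
                best = i
                break
        assert best == 14
        assert trim_adapter(read, ADAPTER) == read[:best]

    def test_short_partial_overlap_kept(self):
        read = "ACGTACGTACGTAC" + ADAPTER[:5]
        assert trim_adapter(read, ADAPTER, min_overlap=6) == read

    def test_empty_read_errors(self):
        with pytest.raises(ValueError):
            trim_adapter("", ADAPTER)

    @pytest.mark.parametrize(
        "length,keep", [(13, False), (14, True), (0, False), (30, True)]
    )
    def test_minimum_insert_boundary(self, length, keep):
        assert filter_insert("A" * length) is keep


class TestCandidatesAndWeights:
    def test_overlapping_read_is_candidate(self, plus_locus, default_params):
        index = build_locus_index([plus_locus])
        got = find_candidate_loci(seg(1000, 1020), index, default_params)
        assert got == {"mir-x"}

    def test_gap_boundary_50_in_51_out(self, plus_locus, default_params):
        index = build_locus_index([plus_locus])
        assert find_candidate_loci(seg(920, 940), index, default_params) == {"mir-x"}
        assert find_candidate_loci(seg(919, 939), index, default_params) == set()

    def test_antisense_read_never_assigned(self, plus_locus, default_params):
        index = build_locus_index([plus_locus])
        assert find_candidate_loci(seg(1000, 1020, "-"), index, default_params) == set()

    def test_unknown_chromosome_empty_with_warning(self, plus_locus, default_params, caplog):
        index = build_locus_index([plus_locus])
        with caplog.at_level("WARNING"):
            got = find_candidate_loci(seg(0, 20, chrom="chrUn"), index, default_params)
        assert got == set()
        assert "unknown chromosome" in caplog.text

    @pytest.mark.parametrize("n", [1, 2, 4, 7])
    def test_even_allotment_sums_to_one(self, n):
        assignments = allot_weights("r1", [f"l{i}" for i in range(n)])
        assert len(assignments) == n
        assert all(a.weight == pytest.approx(1.0 / n) for a in assignments)
        assert sum(a.weight for a in assignments) == pytest.approx(1.0)

    def test_no_candidates_no_assignments(self):
        assert allot_weights("r1", []) == []


class TestClassify:
    def test_mir5p_containment(self, plus_locus):
        rs = derive_regions(plus_locus)
        assert classify(seg(998, 1019), rs) is Category.MIR5P

    def test_mor5p_containment(self, plus_locus):
        rs = derive_regions(plus_locus)
        assert classify(seg(970, 990), rs) is Category.MOR5P

    def test_loop_read_unassigned(self, plus_locus):
        rs = derive_regions(plus_locus)
        assert classify(seg(1030, 1050), rs) is Category.UNASSIGNED

    def test_strand_mismatch_unassigned(self, plus_locus):
        rs = derive_regions(plus_locus)
        assert classify(seg(998, 1019, "-"), rs) is Category.UNASSIGNED

    def test_boundary_read_spanning_full_window_included(self, plus_locus):
        rs = derive_regions(plus_locus)
        w = rs.mir5p_win
        assert classify(seg(w.start, w.end), rs) is Category.MIR5P
        assert classify(seg(w.start - 1, w.end), rs) is Category.UNASSIGNED

    def test_exclusivity_exhaustive_for_kept_lengths(self, plus_locus, default_params):
        """No read of length >= min_insert fits in both a miR and a moR window."""
        rs = derive_regions(plus_locus, default_params)
        windows = [rs.mir5p_win, rs.mir3p_win, rs.mor5p_win, rs.mor3p_win]
        lo = min(w.start for w in windows)
        hi = max(w.end for w in windows)
        for length in range(default_params.min_insert, 31):
            for start in range(lo, hi - length + 1):
                read = GenomicInterval("chr1", start, start + length, "+")
                holders = [w for w in windows if w.contains(read)]
                assert len(holders) <= 1


class TestTabulateAndRpmr:
    def test_empty_input_empty_table(self):
        assert tabulate([], "lib").counts == {}

    def test_single_read_counts_one(self):
        table = tabulate(
            [(LocusAssignment("r1", "l1", 1.0), Category.MIR5P)], "lib"
        )
        assert table.counts == {("l1", Category.MIR5P): 1.0}

    def test_split_read_conserves_total(self):
        pairs = [
            (LocusAssignment("r1", "l1", 0.5), Category.MOR5P),
            (LocusAssignment("r1", "l2", 0.5), Category.MOR5P),
        ]
        table = tabulate(pairs, "lib")
        assert table.counts[("l1", Category.MOR5P)] == 0.5
        assert table.counts[("l2", Category.MOR5P)] == 0.5
        assert table.total() == pytest.approx(1.0)

    def test_unassigned_excluded_from_denominator(self):
        pairs = [
            (LocusAssignment("r1", "l1", 1.0), Category.MIR5P),
            (LocusAssignment("r2", "l1", 1.0), Category.UNASSIGNED),
        ]
        assert tabulate(pairs, "lib").total() == 1.0

    def test_rpmr_identity_denominator(self):
        table = tabulate(
            [(LocusAssignment(f"r{i}", "l1", 1.0), Category.MIR5P) for i in range(4)],
            "lib",
        )
        rpmr = normalize_rpmr(table)
        assert rpmr.rpmr[("l1", Category.MIR5P)] == pytest.approx(1e6)

    def test_rpmr_halved_denominator(self):
        pairs = [(LocusAssignment(f"r{i}", "l1", 1.0), Category.MIR5P) for i in range(2)]
        pairs += [(LocusAssignment("r9", "l2", 1.0), Category.MOR3P)] * 2
        rpmr = normalize_rpmr(tabulate(pairs, "lib"))
        assert rpmr.rpmr[("l1", Category.MIR5P)] == pytest.approx(0.5e6)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="no region-mapped reads"):
            normalize_rpmr(tabulate([], "lib"))

    @given(
        weights=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=3),  # locus
                st.integers(min_value=0, max_value=3),  # category
            ),
            min_size=1, max_size=50,
        )
    )
    def test_rpmr_always_sums_to_one_million(self, weights):
        cats = list(Category)[:4]
        pairs = [
            (LocusAssignment(f"r{i}", f"l{l}", 1.0), cats[c])
            for i, (l, c) in enumerate(weights)
        ]
        rpmr = normalize_rpmr(tabulate(pairs, "lib"))
        assert sum(rpmr.rpmr.values()) == pytest.approx(1e6)


class TestQuantifyPipeline:
    def test_read_near_two_loci_split_evenly(self, default_params):
        from morna import MatureMir, PriMirLocus

        def locus(lid, start):
            # hairpin: 5p mature at the very start, 3p mature at the very end
            return PriMirLocus(
                lid, GenomicInterval("chr1", start, start + 60, "+"),
                mature_5p=MatureMir(f"{lid}-5p", "5p",
                                    GenomicInterval("chr1", start, start + 20, "+")),
                mature_3p=MatureMir(f"{lid}-3p", "3p",
                                    GenomicInterval("chr1", start + 40, start + 60, "+")),
            )

        a, b = locus("a", 1000), locus("b", 1120)  # gap of 60 between hairpins
        # read in the gap: inside a's 3p-moR window, within 50 of both
        read = seg(1070, 1090, read_id="rx")
        result = quantify([read], [a, b], default_params)
        assert result.counts.counts == {("a", Category.MOR3P): 0.5}
        assert result.n_assigned_reads == 1

    def test_multiple_alignments_pool_candidates(self, plus_locus, default_params):
        other = seg(5000, 5020, read_id="rx")  # far from any locus
        near = seg(1000, 1020, read_id="rx")
        result = quantify([other, near], [plus_locus], default_params)
        assert result.counts.counts == {("mir-x", Category.MIR5P): 1.0}
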