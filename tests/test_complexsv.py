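"""Complex-SV pipeline: junction truth table, consolidation, annotation."""
import numpy as np
import pytest

from comsv.calls import SVCall
from comsv.complexsv import (
    BreakPointCall,
    ComplexParams,
    annotate_and_deduplicate,
    call_from_contigs,
    call_from_split_sets,
    classify_junction,
    cluster_breakpoints,
    consolidate_breakpoints,
    find_cross_pipeline_duplicates,
    make_junctions,
)
from comsv.complexsv.annotate import GeneInterval
from comsv.formats.maps import AlignmentRecord, SplitAlignmentSet


def _seg(ref_id, orientation, q0, q1, r0, r1, pairs, qid="mol1"):
    return AlignmentRecord(qid, ref_id, orientation, q0, q1, r0, r1, pairs)


def _junction(left, right, params=None):
    ss = SplitAlignmentSet.from_records([left, right])
    (jn,) = make_junctions(ss, params)
    return jn


PARAMS = ComplexParams()


def _plus(ref, q0, q1, r0, r1, first_site, qid="mol1", first_q=1):
    n = 3
    pairs = [(first_site + i, first_q + i) for i in range(n)]
    return _seg(ref, "+", q0, q1, r0, r1, pairs, qid=qid)


def _minus(ref, q0, q1, r0, r1, first_site, qid="mol1", first_q=1):
    n = 3
    pairs = [(first_site + i, first_q + n - 1 - i) for i in range(n)]
    return _seg(ref, "-", q0, q1, r0, r1, pairs, qid=qid)


class TestClassifyJunction:
    def test_different_chromosomes_is_inter_translocation(self):
        # left on one chromosome '+', right on another '+'
        left = _plus("chr21", 0, 50_000, 1_000_000, 1_050_000, 10)
        right = _plus("chr13", 51_000, 100_000, 2_000_000, 2_049_000, 40, first_q=4)
        call = classify_junction(_junction(left, right), PARAMS)
        assert call is not None
        assert call.inferred_type == "tra_inter_bp"
        assert {call.locus_a[0], call.locus_b[0]} == {"chr21", "chr13"}

    def test_orientation_flip_is_inversion(self):
        left = _plus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
        right = _minus("chr1", 51_000, 100_000, 1_051_000, 1_100_000, 13, first_q=4)
        call = classify_junction(_junction(left, right), PARAMS)
        assert call is not None
        assert call.inferred_type == "inversion_bp"
        assert call.pattern == "+-"

    def test_ref_overlap_with_shared_sites_is_duplication(self):
        left = _seg("chr1", "+", 0, 50_000, 1_000_000, 1_050_000,
                    [(10, 1), (11, 2), (12, 3)])
        right = _seg("chr1", "+", 51_000, 100_000, 1_030_000, 1_090_000,
                     [(11, 4), (12, 5), (13, 6)])
        call = classify_junction(_junction(left, right), PARAMS)
        assert call is not None
        assert call.inferred_type == "dup_bp"
        assert call.unit is not None

    def test_collinear_large_ref_gap_is_large_deletion(self):
        left = _plus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
        right = _plus("chr1", 51_000, 100_000, 1_151_000, 1_200_000, 20, first_q=4)
        call = classify_junction(_junction(left, right), PARAMS)
        assert call is not None
        assert call.inferred_type == "large_del_bp"
        assert call.size_bp == pytest.approx(100_000, rel=0.05)

    def test_collinear_huge_ref_gap_is_intra_translocation(self):
        left = _plus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
        right = _plus("chr1", 51_000, 100_000, 1_351_000, 1_400_000, 30, first_q=4)
        call = classify_junction(_junction(left, right), PARAMS)
        assert call is not None
        assert call.inferred_type == "tra_intra_bp"

    def test_large_query_gap_is_large_insertion(self):
        left = _plus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
        right = _plus("chr1", 151_000, 200_000, 1_051_000, 1_100_000, 20, first_q=4)
        call = classify_junction(_junction(left, right), PARAMS)
        assert call is not None
        assert call.inferred_type == "large_ins_bp"

    def test_reordered_segments_far_apart_is_intra_translocation(self):
        left = _plus("chr1", 0, 50_000, 2_000_000, 2_050_000, 200)
        right = _plus("chr1", 51_000, 100_000, 1_000_000, 1_049_000, 10, first_q=4)
        call = classify_junction(_junction(left, right), PARAMS)
        assert call is not None
        assert call.inferred_type == "tra_intra_bp"

    def test_collinear_small_gap_is_no_call(self):
        left = _plus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
        right = _plus("chr1", 51_000, 100_000, 1_052_000, 1_100_000, 14, first_q=4)
        assert classify_junction(_junction(left, right), PARAMS) is None

    def test_query_overlap_beyond_slack_rejected(self):
        left = _plus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
        right = _plus("chr1", 30_000, 100_000, 1_300_000, 1_370_000, 20, first_q=4)
        ss = SplitAlignmentSet.from_records([left, right], overlap_slack_bp=25_000)
        assert make_junctions(ss, PARAMS) == []

    def test_exhaustive_truth_table(self):
        """Grid over {same/different ref} x orientation patterns x gap
        regimes, checked against a hand-written expectation table."""
        gap_regimes = {
            "collinear": 2_000.0,
            "large_del": 120_000.0,
            "huge": 450_000.0,
        }
        table = {
            # (same_ref, pattern, regime) -> expected type (None = no call)
            ("diff", "++", "collinear"): "tra_inter_bp",
            ("diff", "+-", "collinear"): "tra_inter_bp",
            ("diff", "-+", "collinear"): "tra_inter_bp",
            ("diff", "--", "collinear"): "tra_inter_bp",
            ("same", "+-", "collinear"): "inversion_bp",
            ("same", "-+", "collinear"): "inversion_bp",
            ("same", "+-", "large_del"): "inversion_bp",
            ("same", "-+", "large_del"): "inversion_bp",
            ("same", "++", "collinear"): None,
            ("same", "--", "collinear"): None,
            ("same", "++", "large_del"): "large_del_bp",
            ("same", "--", "large_del"): "large_del_bp",
            ("same", "++", "huge"): "tra_intra_bp",
            ("same", "--", "huge"): "tra_intra_bp",
        }
        for (same, pattern, regime), expected in table.items():
            gap = gap_regimes[regime]
            ref_b = "chr1" if same == "same" else "chr2"
            o1, o2 = pattern
            if o1 == "+":
                left = _plus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
                left_inner = 1_050_000
            else:
                left = _minus("chr1", 0, 50_000, 1_000_000, 1_050_000, 10)
                left_inner = 1_000_000
            # place the right segment 'gap' along the reading direction
            if o2 == "+":
                r0 = left_inner + gap if o1 == "+" else left_inner + gap
                right = _plus(ref_b, 51_000, 100_000, r0, r0 + 49_000, 100, first_q=4)
            else:
                r1 = left_inner + gap if o1 == "+" else left_inner - gap
                if o1 == "-" and o2 == "-":
                    # reading '-' then '-': ref coordinates keep decreasing
                    r1 = left_inner - gap
                    right = _minus(ref_b, 51_000, 100_000, r1 - 49_000, r1, 2, first_q=4)
                else:
                    right = _minus(ref_b, 51_000, 100_000, r1, r1 + 49_000, 100, first_q=4)
            call = classify_junction(_junction(left, right), PARAMS)
            got = call.inferred_type if call else None
            assert got == expected, (same, pattern, regime, got, expected)


class TestSplitSetCalls:
    def test_three_segment_foreign_middle_gives_two_bps_and_full_span(self):
        a = _plus("chr21", 0, 50_000, 1_000_000, 1_050_000, 10)
        b = _plus("chr13", 51_000, 150_000, 5_000_000, 5_099_000, 500, first_q=4)
        c = _plus("chr21", 151_000, 200_000, 1_051_000, 1_100_000, 20, first_q=7)
        ss = SplitAlignmentSet.from_records([a, b, c])
        calls, fulls = call_from_split_sets([ss])
        assert sum(c.inferred_type == "tra_inter_bp" for c in calls) == 2
        assert len(fulls) == 1
        assert fulls[0].sv_type == "translocation_inter"

    def test_single_segment_molecules_give_no_calls(self):
        a = _plus("chr21", 0, 50_000, 1_000_000, 1_050_000, 10)
        ss = SplitAlignmentSet.from_records([a])
        calls, fulls = call_from_split_sets([ss])
        assert calls == [] and fulls == []


class TestContigCalls:
    def test_contig_split_between_chromosomes(self):
        a = _plus("chr16", 0, 500_000, 1_000_000, 1_500_000, 10, qid="ctg1")
        b = _plus("chr6", 501_000, 900_000, 7_000_000, 7_399_000, 700, qid="ctg1",
                  first_q=4)
        calls, _ = call_from_contigs([a, b])
        (call,) = calls
        assert call.inferred_type == "tra_inter_bp"
        assert call.source == "contig"

    def test_contig_opposite_orientations_same_ref(self):
        a = _plus("chr16", 0, 500_000, 1_000_000, 1_500_000, 10, qid="ctg1")
        b = _minus("chr16", 501_000, 900_000, 3_000_000, 3_399_000, 700,
                   qid="ctg1", first_q=4)
        calls, _ = call_from_contigs([a, b])
        (call,) = calls
        assert call.inferred_type == "inversion_bp"

    def test_collinear_contig_gives_no_calls(self):
        a = _plus("chr16", 0, 500_000, 1_000_000, 1_500_000, 10, qid="ctg1")
        b = _plus("chr16", 501_000, 900_000, 1_501_000, 1_900_000, 100,
                  qid="ctg1", first_q=4)
        calls, _ = call_from_contigs([a, b])
        assert calls == []


def _bp(itype, ref, pos_a, pos_b, mol, pattern="", source="split", **kw):
    return BreakPointCall(
        (ref, pos_a, "L"), (ref, pos_b, "R"), itype, [mol], source,
        pattern=pattern, **kw,
    )


class TestConsolidate:
    def test_two_inversion_boundary_clusters_make_complete_inversion(self):
        calls = []
        for i in range(4):
            calls.append(_bp("inversion_bp", "chr1", 1_000_000 + i * 50,
                             1_200_000 + i * 50, f"a{i}", pattern="+-"))
            calls.append(_bp("inversion_bp", "chr1", 1_001_000 + i * 50,
                             1_201_000 + i * 50, f"b{i}", pattern="-+"))
        complex_calls, _ = consolidate_breakpoints(calls)
        (inv,) = complex_calls
        assert inv.sv_type == "inversion"
        assert inv.status == "complete"
        assert len(inv.supporting_molecules) == 8

    def test_lone_dup_cluster_is_partial(self):
        calls = [
            _bp("dup_bp", "chr1", 2_000_000, 2_030_000, f"m{i}",
                unit=(2_000_000.0, 2_030_000.0))
            for i in range(4)
        ]
        complex_calls, _ = consolidate_breakpoints(calls)
        (dup,) = complex_calls
        assert dup.sv_type == "duplication"
        assert dup.status == "partial"

    def test_full_span_dup_member_promotes_to_complete(self):
        calls = [
            _bp("dup_bp", "chr1", 2_000_000, 2_030_000, f"m{i}",
                unit=(2_000_000.0, 2_030_000.0), full_span=(i == 0))
            for i in range(4)
        ]
        complex_calls, _ = consolidate_breakpoints(calls)
        assert complex_calls[0].status == "complete"

    def test_clusters_below_support_threshold_dropped(self):
        calls = [_bp("inversion_bp", "chr1", 1_000_000, 1_100_000, "only",
                     pattern="+-")]
        complex_calls, _ = consolidate_breakpoints(calls)
        assert complex_calls == []

    def test_large_indel_junctions_routed_to_indel_namespace(self):
        calls = [
            _bp("large_del_bp", "chr1", 1_000_000, 1_100_000, f"m{i}",
                size_bp=95_000.0)
            for i in range(5)
        ]
        complex_calls, junction_indels = consolidate_breakpoints(calls)
        assert complex_calls == []
        (jdel,) = junction_indels
        assert jdel.sv_type == "deletion"
        assert jdel.size_bp == pytest.approx(95_000.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_cluster_positions_match_bruteforce_1d_oracle(self, seed):
        rng = np.random.default_rng(seed)
        true_loci = np.sort(rng.uniform(0, 5e6, 5))
        # keep loci well separated relative to the merge window
        while np.any(np.diff(true_loci) < 200_000):
            true_loci = np.sort(rng.uniform(0, 5e6, 5))
        calls = []
        assignments = []
        for i in range(100):
            locus = int(rng.integers(5))
            jitter = rng.uniform(-10_000, 10_000)
            calls.append(_bp("large_del_bp", "chr1", true_loci[locus] + jitter,
                             true_loci[locus] + 60_000 + jitter, f"m{i}",
                             size_bp=60_000.0))
            assignments.append(locus)
        clusters = cluster_breakpoints(calls)
        assert len(clusters) == 5
        got = sorted(c.pos_a for c in clusters)
        # oracle: per true locus, the plain median of its jittered calls
        expect = []
        for locus in range(5):
            vals = sorted(
                c.locus_a[1] for c, a in zip(calls, assignments) if a == locus
            )
            expect.append(np.median(vals))
        for g, e in zip(got, sorted(expect)):
            assert g == pytest.approx(e, abs=1_500.0)


class TestAnnotateDeduplicate:
    def _dup_call(self):
        return SVCall(
            call_id="complex_0", sv_type="duplication", ref_id="chr1",
            start_bp=2_000_000.0, end_bp=2_004_000.0, size_bp=4_000.0,
            support=10, total=10, status="complete", confidence=0.9,
            source="complex",
        )

    def _ins_call(self, start=2_001_000.0, size=4_000.0):
        return SVCall(
            call_id="indel_0", sv_type="insertion", ref_id="chr1",
            start_bp=start, end_bp=start, size_bp=size, support=8, total=20,
            status="complete", confidence=0.8, source="indel",
            region_start_bp=start - 10_000.0, region_end_bp=start + 10_000.0,
        )

    def test_insertion_inside_matching_dup_subsumed(self):
        out = annotate_and_deduplicate([self._dup_call()], [self._ins_call()])
        types = [c.sv_type for c in out]
        assert types == ["duplication"]
        assert find_cross_pipeline_duplicates(out) == []

    def test_insertion_with_incompatible_size_kept(self):
        ins = self._ins_call(size=40_000.0)
        out = annotate_and_deduplicate([self._dup_call()], [ins])
        assert sorted(c.sv_type for c in out) == ["duplication", "insertion"]

    def test_insertion_far_away_kept(self):
        ins = self._ins_call(start=4_000_000.0)
        out = annotate_and_deduplicate([self._dup_call()], [ins])
        assert sorted(c.sv_type for c in out) == ["duplication", "insertion"]

    def test_gene_overlap_annotation_half_open(self):
        genes = [
            GeneInterval("CSMD1_like", "chr1", 2_003_000.0, 2_500_000.0),
            GeneInterval("other", "chr1", 2_004_000.0, 2_500_000.0),
            GeneInterval("elsewhere", "chr2", 1.0, 1e6),
        ]
        dup = self._dup_call()  # interval [2e6, 2004000)
        out = annotate_and_deduplicate([dup], [], genes=genes)
        assert out[0].genes == ["CSMD1_like"]

    def test_junction_indel_folded_into_pipeline_call(self):
        pipeline_del = SVCall(
            call_id="indel_1", sv_type="deletion", ref_id="chr1",
            start_bp=1_000_000.0, end_bp=1_060_000.0, size_bp=60_000.0,
            support=9, total=30, status="complete", confidence=0.9,
            source="indel", supporting_molecules=[f"m{i}" for i in range(9)],
        )
        junction_del = SVCall(
            call_id="junction_indel_0", sv_type="deletion", ref_id="chr1",
            start_bp=1_001_000.0, end_bp=1_059_000.0, size_bp=58_000.0,
            support=4, total=4, status="complete", confidence=0.6,
            source="complex-junction",
            supporting_molecules=["m0", "x1", "x2", "x3"],
        )
        out = annotate_and_deduplicate([], [pipeline_del, junction_del])
        assert len(out) == 1
        assert out[0].call_id == "indel_1"
        assert out[0].support == 12  # molecule union
        assert find_cross_pipeline_duplicates(out) == []
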