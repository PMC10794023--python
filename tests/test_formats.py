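"""Format layer: data-type invariants, BNX/CMAP/XMAP round-trips, parsing."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comsv.formats import (
    AlignmentRecord,
    BnxParseError,
    LabelMap,
    SplitAlignmentSet,
    XmapParseError,
    group_split_sets,
    parse_alignment_string,
    read_bnx,
    read_cmap,
    read_xmap,
    write_bnx,
    write_cmap,
    write_xmap,
)

from conftest import random_label_maps


class TestLabelMap:
    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            LabelMap("m", 0.0, [])

    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError):
            LabelMap("m", 100.0, [50.0, 40.0])

    def test_rejects_positions_beyond_length(self):
        with pytest.raises(ValueError):
            LabelMap("m", 100.0, [50.0, 150.0])

    def test_value_equality_within_tolerance(self):
        a = LabelMap("m", 100.0, [10.0, 20.0])
        b = LabelMap("m", 100.0, [10.05, 20.0])
        assert a == b


class TestAlignmentRecord:
    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            AlignmentRecord("q", "r", "+", 1, 2, 1, 2, [(1, 1)])

    def test_minus_orientation_query_decreasing(self):
        rec = AlignmentRecord("q", "r", "-", 30.0, 10.0, 10.0, 30.0,
                              [(1, 3), (2, 2), (3, 1)])
        assert [q for _, q in rec.query_ordered_pairs()] == [1, 2, 3]

    def test_minus_orientation_rejects_increasing_query(self):
        with pytest.raises(ValueError):
            AlignmentRecord("q", "r", "-", 1, 2, 1, 2, [(1, 1), (2, 2)])


class TestSplitAlignmentSet:
    def _rec(self, q0, q1, r0, r1):
        return AlignmentRecord("q", "r", "+", q0, q1, r0, r1, [(1, 1), (2, 2)])

    def test_unaligned_intervals_tile_the_molecule(self):
        segs = [self._rec(1000, 5000, 1, 2), self._rec(8000, 12000, 5, 6)]
        ss = SplitAlignmentSet.from_records(segs, query_length_bp=15_000)
        assert ss.unaligned_intervals == [(0.0, 1000.0), (5000.0, 8000.0),
                                         (12_000.0, 15_000.0)]
        covered = sum(q1 - q0 for q0, q1 in ss.unaligned_intervals)
        covered += sum(
            abs(s.query_end_bp - s.query_start_bp) for s in ss.segments
        )
        assert covered == pytest.approx(15_000.0)

    def test_excessive_query_overlap_rejected(self):
        segs = [self._rec(1000, 5000, 1, 2), self._rec(2000, 9000, 5, 6)]
        with pytest.raises(ValueError):
            SplitAlignmentSet.from_records(segs, overlap_slack_bp=500)


class TestBnx:
    def test_round_trip_two_molecules(self, tmp_path):
        mols = [
            LabelMap("1", 150_000.0, [5000.0, 42_000.5, 99_999.9]),
            LabelMap("2", 80_000.0, [10.5, 70_000.0]),
        ]
        p = tmp_path / "two.bnx"
        write_bnx(mols, p)
        back = read_bnx(p)
        assert back == mols

    def test_length_sentinel_dropped(self, tmp_path):
        p = tmp_path / "s.bnx"
        p.write_text("# BNX File Version:\t1.2\n0\t7\t50000.0\n"
                     "1\t1000.0\t2500.0\t50000.0\n")
        (mol,) = read_bnx(p)
        # hand count: two real labels, the trailing 50000.0 is the sentinel
        assert mol.n_labels == 2
        assert np.allclose(mol.positions, [1000.0, 2500.0])

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bnx"
        p.write_text("# BNX File Version:\t1.2\n# Label Channels:\t1\n")
        assert read_bnx(p) == []

    def test_zero_label_molecule_writes_sentinel_only(self, tmp_path):
        p = tmp_path / "z.bnx"
        write_bnx([LabelMap("9", 42_000.0, [])], p)
        label_lines = [l for l in p.read_text().splitlines() if l.startswith("1\t")]
        assert label_lines == ["1\t42000.0"]
        (mol,) = read_bnx(p)
        assert mol.n_labels == 0

    def test_line_count_scales_with_molecules(self, tmp_path, rng):
        mols = random_label_maps(rng, 200)
        p = tmp_path / "many.bnx"
        write_bnx(mols, p)
        lines = p.read_text().splitlines()
        header = sum(1 for l in lines if l.startswith("#"))
        assert len(lines) == header + 2 * len(mols)

    def test_label_line_before_header_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.bnx"
        p.write_text("# BNX File Version:\t1.2\n1\t100.0\t200.0\n")
        with pytest.raises(BnxParseError, match="line 2"):
            read_bnx(p)

    def test_non_monotone_molecule_skipped_with_warning(self, tmp_path):
        p = tmp_path / "nm.bnx"
        p.write_text(
            "0\t1\t9000.0\n1\t500.0\t400.0\t9000.0\n"
            "0\t2\t9000.0\n1\t100.0\t200.0\t9000.0\n"
        )
        with pytest.warns(UserWarning, match="non-monotone"):
            mols = read_bnx(p)
        assert [m.map_id for m in mols] == ["2"]

    def test_short_molecules_flagged_but_kept(self, tmp_path):
        p = tmp_path / "short.bnx"
        write_bnx([LabelMap("1", 10_000.0, [500.0, 600.0])], p)
        (mol,) = read_bnx(p, min_length_bp=50_000.0)
        assert mol.flagged_short

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_property(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        mols = random_label_maps(rng, 5)
        p = tmp_path_factory.mktemp("bnx") / "r.bnx"
        write_bnx(mols, p)
        assert read_bnx(p) == mols


class TestCmap:
    def test_round_trip(self, tmp_path, rng):
        maps = random_label_maps(rng, 4)
        p = tmp_path / "r.cmap"
        write_cmap(maps, p)
        assert read_cmap(p) == maps


class TestXmap:
    def test_alignment_string_parse(self):
        assert parse_alignment_string("(1,1)(2,2)(4,3)") == [(1, 1), (2, 2), (4, 3)]

    def test_unbalanced_alignment_string_rejected(self):
        with pytest.raises(XmapParseError):
            parse_alignment_string("(1,1)(2,2")

    def _records(self):
        return [
            AlignmentRecord("10", "1", "+", 100.0, 5000.0, 200.0, 5100.0,
                            [(1, 1), (2, 2), (4, 3)], confidence=12.5),
            AlignmentRecord("11", "1", "-", 4000.0, 100.0, 200.0, 4100.0,
                            [(1, 9), (2, 8), (3, 7)], confidence=9.0),
        ]

    def test_round_trip(self, tmp_path):
        p = tmp_path / "r.xmap"
        write_xmap(self._records(), p)
        back = read_xmap(p)
        for orig, rec in zip(self._records(), back):
            assert rec.query_id == orig.query_id
            assert rec.ref_id == orig.ref_id
            assert rec.orientation == orig.orientation
            assert rec.site_pairs == orig.site_pairs
            assert rec.confidence == pytest.approx(orig.confidence, abs=0.01)
            assert rec.query_start_bp == pytest.approx(orig.query_start_bp, abs=0.1)

    def test_minus_records_have_decreasing_query_sites(self, tmp_path):
        p = tmp_path / "m.xmap"
        write_xmap(self._records(), p)
        minus = [r for r in read_xmap(p) if r.orientation == "-"][0]
        qs = [q for _, q in minus.site_pairs]
        assert qs == sorted(qs, reverse=True)

    def test_group_split_sets_tiles_query(self, tmp_path):
        recs = [
            AlignmentRecord("7", "1", "+", 0.0, 30_000.0, 1000.0, 31_000.0,
                            [(1, 1), (4, 5)]),
            AlignmentRecord("7", "2", "+", 40_000.0, 90_000.0, 500.0, 50_500.0,
                            [(2, 6), (9, 14)]),
        ]
        (ss,) = group_split_sets(recs, query_lengths={"7": 100_000.0})
        assert len(ss.segments) == 2
        assert ss.unaligned_intervals == [(30_000.0, 40_000.0), (90_000.0, 100_000.0)]
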