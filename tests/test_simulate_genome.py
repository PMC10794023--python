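"""Derived-genome construction: SV application, liftover, clone inheritance."""
import numpy as np
import pytest

from comsv.formats.maps import LabelMap
from comsv.simulate import (
    CloneGraph,
    SVEvent,
    apply_svs_to_map,
    build_clone_genomes,
    build_haplotype_genome,
)


def _ref(positions, length=100_000.0, map_id="chrT"):
    return LabelMap(map_id, length, positions)


def _sv(sv_type, start, end, size=0.0, novel=None, **kw):
    return SVEvent(
        sv_id=kw.pop("sv_id", "e1"),
        sv_type=sv_type,
        ref_id=kw.pop("ref_id", "chrT"),
        start_bp=start,
        end_bp=end,
        size_bp=size,
        zygosity=kw.pop("zygosity", "hom"),
        novel_label_offsets=novel,
        **kw,
    )


def segment_concat_oracle(ref: LabelMap, svs: list[SVEvent]) -> list[float]:
    """Independent oracle: rebuild the haplotype by concatenating literal
    per-label segment lists."""
    svs = sorted(svs, key=lambda s: s.start_bp)
    labels = [(float(p), "ref") for p in ref.positions]

    def take(lo, hi):
        return [(p, t) for p, t in labels if lo <= p < hi]

    out = []
    offset = 0.0
    cursor = 0.0
    for sv in svs:
        for p, _ in take(cursor, sv.start_bp):
            out.append(offset + (p - cursor))
        offset += sv.start_bp - cursor
        if sv.sv_type == "deletion":
            pass
        elif sv.sv_type == "insertion":
            for o in sorted(sv.novel_label_offsets):
                out.append(offset + o)
            offset += sv.size_bp
        elif sv.sv_type == "inversion":
            span = sv.end_bp - sv.start_bp
            inner = [offset + (sv.end_bp - p) for p, _ in take(sv.start_bp, sv.end_bp)]
            out.extend(sorted(inner))
            offset += span
        elif sv.sv_type == "duplication":
            span = sv.end_bp - sv.start_bp
            for rep in range(2):
                for p, _ in take(sv.start_bp, sv.end_bp):
                    out.append(offset + (p - sv.start_bp))
                offset += span
        cursor = sv.end_bp
    for p, _ in take(cursor, ref.length_bp + 1):
        out.append(offset + (p - cursor))
    return sorted(out)


class TestApplySvs:
    def test_deletion_shifts_downstream_labels(self):
        ref = _ref([9_000.0, 11_000.0, 15_000.0])
        hap, lift = apply_svs_to_map(ref, [_sv("deletion", 10_000.0, 13_700.0, 3_700.0)])
        assert hap.positions.tolist() == [9_000.0, 11_300.0]

    def test_inversion_mirrors_offsets_and_reverses_order(self):
        ref = _ref([20_000.0, 21_000.0, 24_000.0, 28_000.0, 40_000.0])
        hap, lift = apply_svs_to_map(ref, [_sv("inversion", 20_500.0, 30_500.0)])
        # labels inside [20500, 30500) at offsets 500, 3500, 7500 from span
        # start map to mirrored offsets 10000-500 etc., order reversed
        inside = hap.positions[(hap.positions > 20_500) & (hap.positions < 30_500)]
        assert inside.tolist() == pytest.approx([20_500 + 2_500, 20_500 + 6_500, 20_500 + 9_500])
        src = lift.src_pos[(lift.out_pos > 20_500) & (lift.out_pos < 30_500)]
        assert src.tolist() == pytest.approx([28_000.0, 24_000.0, 21_000.0])

    def test_insertion_shifts_and_splices_novel_labels(self):
        ref = _ref([10_000.0, 30_000.0])
        sv = _sv("insertion", 20_000.0, 20_000.0, 5_000.0, novel=np.array([1_000.0, 4_000.0]))
        hap, lift = apply_svs_to_map(ref, [sv])
        assert hap.positions.tolist() == [10_000.0, 21_000.0, 24_000.0, 35_000.0]
        assert lift.src_site.tolist() == [1, -1, -1, 2]
        assert hap.length_bp == pytest.approx(105_000.0)

    def test_duplication_splices_copy_after_span(self):
        ref = _ref([10_000.0, 12_000.0, 30_000.0])
        hap, _ = apply_svs_to_map(ref, [_sv("duplication", 9_000.0, 13_000.0, 4_000.0)])
        assert hap.positions.tolist() == [10_000.0, 12_000.0, 14_000.0, 16_000.0, 34_000.0]

    def test_span_exceeding_map_rejected(self):
        ref = _ref([10_000.0])
        with pytest.raises(ValueError, match="exceeds"):
            apply_svs_to_map(ref, [_sv("deletion", 90_000.0, 120_000.0, 30_000.0)])

    def test_overlapping_svs_rejected(self):
        ref = _ref([10_000.0])
        svs = [
            _sv("deletion", 10_000.0, 20_000.0, 10_000.0, sv_id="a"),
            _sv("inversion", 15_000.0, 40_000.0, sv_id="b"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            apply_svs_to_map(ref, svs)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_sv_set_matches_segment_concat_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = 2_000_000.0
        ref = _ref(np.sort(rng.uniform(1, length - 1, 150)), length=length)
        svs = []
        cursor = 20_000.0
        for i in range(50):
            gap = rng.uniform(5_000, 20_000)
            size = rng.uniform(2_000, 15_000)
            kind = rng.choice(["deletion", "insertion", "inversion", "duplication"])
            start = cursor + gap
            if start + size > length - 30_000:
                break
            if kind == "insertion":
                novel = np.sort(rng.uniform(1, size - 1, rng.integers(0, 4)))
                svs.append(_sv("insertion", start, start, size, novel=novel, sv_id=f"s{i}"))
                cursor = start
            else:
                svs.append(_sv(kind, start, start + size, size, sv_id=f"s{i}"))
                cursor = start + size
        hap, lift = apply_svs_to_map(ref, svs)
        oracle = segment_concat_oracle(ref, svs)
        assert np.allclose(hap.positions, oracle)

    def test_label_count_conservation_for_deletions(self, rng):
        length = 1_000_000.0
        ref = _ref(np.sort(rng.uniform(1, length - 1, 100)), length=length)
        svs = [
            _sv("deletion", s, s + 8_000.0, 8_000.0, sv_id=f"d{i}")
            for i, s in enumerate(np.arange(50_000.0, 800_000.0, 100_000.0))
        ]
        hap, lift = apply_svs_to_map(ref, svs)
        deleted = sum(
            int(np.searchsorted(ref.positions, sv.end_bp) - np.searchsorted(ref.positions, sv.start_bp))
            for sv in svs
        )
        assert hap.n_labels == ref.n_labels - deleted

    def test_liftover_is_bijective_on_non_novel_labels(self, rng):
        length = 500_000.0
        ref = _ref(np.sort(rng.uniform(1, length - 1, 60)), length=length)
        novel = np.array([500.0, 2_500.0])
        svs = [
            _sv("deletion", 50_000.0, 60_000.0, 10_000.0, sv_id="d"),
            _sv("insertion", 100_000.0, 100_000.0, 5_000.0, novel=novel, sv_id="i"),
            _sv("inversion", 200_000.0, 260_000.0, sv_id="v"),
        ]
        hap, lift = apply_svs_to_map(ref, svs)
        real = lift.src_site[lift.src_site > 0]
        assert len(set(real.tolist())) == real.size  # injective
        surviving = [
            i + 1 for i, p in enumerate(ref.positions) if not (50_000.0 <= p < 60_000.0)
        ]
        assert sorted(real.tolist()) == surviving  # surjective onto survivors


class TestCloneGenomes:
    def _refs(self):
        return {"chrT": _ref(np.arange(5_000.0, 99_000.0, 5_000.0))}

    def test_hom_deletion_on_both_haplotypes(self):
        sv = _sv("deletion", 30_000.0, 36_000.0, 6_000.0, zygosity="hom")
        graph = CloneGraph({"normal": [sv]}, {"normal": None})
        genomes = build_clone_genomes(self._refs(), graph)
        for hap in (0, 1):
            assert "e1" in genomes[("normal", hap)].sv_ids

    def test_het_deletion_on_one_haplotype(self):
        sv = _sv("deletion", 30_000.0, 36_000.0, 6_000.0, zygosity="het", hap=1)
        graph = CloneGraph({"normal": [sv]}, {"normal": None})
        genomes = build_clone_genomes(self._refs(), graph)
        assert "e1" not in genomes[("normal", 0)].sv_ids
        assert "e1" in genomes[("normal", 1)].sv_ids

    def test_trunk_sv_inherited_by_both_subclones(self):
        trunk_sv = _sv("deletion", 30_000.0, 36_000.0, 6_000.0, sv_id="trunk1")
        graph = CloneGraph.linear_cancer_graph([], [trunk_sv], [], [])
        genomes = build_clone_genomes(self._refs(), graph)
        for clone in ("trunk", "subclone1", "subclone2"):
            assert "trunk1" in genomes[(clone, 0)].sv_ids
        assert "trunk1" not in genomes[("normal", 0)].sv_ids

    def test_sv_content_equals_path_union_oracle(self, rng):
        refs = self._refs()
        pool = iter(np.arange(10_000.0, 90_000.0, 4_000.0))
        def mk(i):
            s = next(pool)
            return _sv("deletion", s, s + 2_000.0, 2_000.0, sv_id=f"u{i}")
        private = {
            "normal": [mk(0), mk(1)],
            "trunk": [mk(2), mk(3), mk(4)],
            "subclone1": [mk(5)],
            "subclone2": [mk(6), mk(7)],
        }
        graph = CloneGraph.linear_cancer_graph(**{
            "germline": private["normal"], "trunk": private["trunk"],
            "subclone1": private["subclone1"], "subclone2": private["subclone2"],
        })
        parents = {"normal": None, "trunk": "normal",
                   "subclone1": "trunk", "subclone2": "trunk"}
        for clone in parents:
            expect = set()
            c = clone
            while c is not None:  # oracle: union of private sets along the path
                expect |= {sv.sv_id for sv in private[c]}
                c = parents[c]
            got = {sv.sv_id for sv in graph.sv_set(clone)}
            assert got == expect
            genome = build_haplotype_genome(refs, clone, 0, graph.sv_set(clone))
            assert genome.sv_ids == expect  # all hom -> every hap carries all
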