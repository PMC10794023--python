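"""Junction classification from split alignments.

Two alignment segments adjacent on the query form a junction; its type is
read off the reference ids, orientations and the reference/query gap sizes.
Junction-implied indels below the hand-off threshold are not called here —
they belong to the indel pipeline's namespace.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ..formats.maps import AlignmentRecord, SplitAlignmentSet

__all__ = [
    "ComplexParams",
    "Junction",
    "BreakPointCall",
    "FullSpanRecord",
    "make_junctions",
    "classify_junction",
    "call_from_split_sets",
    "call_from_contigs",
]


@dataclass
class ComplexParams:
    indel_handoff_bp: float = 50_000.0   # junction indels below this -> indel namespace
    tra_intra_min_bp: float = 200_000.0  # discrepancy above this -> intra translocation
    dup_min_overlap: int = 2             # shared matched ref sites for a dup junction
    query_overlap_slack_bp: float = 500.0
    merge_window_bp: float = 30_000.0
    # complementary clusters sit one label-spacing apart at worst, so pairing
    # uses a wider window than same-junction clustering
    pair_window_bp: float = 60_000.0
    min_bp_support: int = 3
    contig_weight: int = 3               # support equivalent when corroborated
    full_span_margin_bp: float = 1_000.0
    dedup_size_tol_frac: float = 0.6
    confidence_halfpoint: int = 4        # support at which confidence = ~0.5


@dataclass
class Junction:
    molecule_id: str
    left: AlignmentRecord   # earlier on the query
    right: AlignmentRecord
    query_gap_bp: float
    inner_left_ref: float   # ref coord of left segment's query-adjacent end
    inner_right_ref: float
    same_ref: bool
    # per-segment ref-site -> molecule label position, when positions known
    left_qpos: dict[int, float] | None = None
    right_qpos: dict[int, float] | None = None

    @property
    def orientation_pattern(self) -> str:
        return self.left.orientation + self.right.orientation


@dataclass
class BreakPointCall:
    locus_a: tuple[str, float, str]  # (ref_id, pos, side)
    locus_b: tuple[str, float, str]
    inferred_type: str
    support: list[str]
    source: str = "split"  # split | realign | contig
    pattern: str = ""
    unit: tuple[float, float] | None = None  # duplication unit span
    size_bp: float = 0.0  # implied size for large indel junctions
    full_span: bool = False


@dataclass
class FullSpanRecord:
    sv_type: str
    ref_id: str
    loci: list[tuple[str, float]]
    molecule_id: str
    source: str = "split"


def _inner_coords(left: AlignmentRecord, right: AlignmentRecord) -> tuple[float, float]:
    inner_left = left.ref_end_bp if left.orientation == "+" else left.ref_start_bp
    inner_right = right.ref_start_bp if right.orientation == "+" else right.ref_end_bp
    return inner_left, inner_right


def make_junctions(
    split_set: SplitAlignmentSet,
    params: ComplexParams | None = None,
    molecule_positions=None,
) -> list[Junction]:
    """Adjacent-segment junctions of one molecule (query-order).

    ``molecule_positions`` (the molecule's label position array, optional)
    enables query-distance-based size estimates, e.g. the tandem-duplication
    unit length.
    """
    params = params or ComplexParams()
    junctions = []
    segs = split_set.segments

    def _qpos_map(seg: AlignmentRecord) -> dict[int, float] | None:
        if molecule_positions is None:
            return None
        return {r: float(molecule_positions[q - 1]) for r, q in seg.site_pairs}

    for left, right in zip(segs, segs[1:]):
        q_hi_left = max(left.query_start_bp, left.query_end_bp)
        q_lo_right = min(right.query_start_bp, right.query_end_bp)
        gap = q_lo_right - q_hi_left
        if gap < -params.query_overlap_slack_bp:
            continue  # rejected: segments overlap on the query beyond slack
        inner_left, inner_right = _inner_coords(left, right)
        junctions.append(
            Junction(
                molecule_id=split_set.query_id,
                left=left,
                right=right,
                query_gap_bp=max(gap, 0.0),
                inner_left_ref=inner_left,
                inner_right_ref=inner_right,
                same_ref=left.ref_id == right.ref_id,
                left_qpos=_qpos_map(left),
                right_qpos=_qpos_map(right),
            )
        )
    return junctions


def _canonical(a: tuple[str, float, str], b: tuple[str, float, str]):
    return (a, b) if (a[0], a[1]) <= (b[0], b[1]) else (b, a)


def classify_junction(
    junction: Junction, params: ComplexParams | None = None, source: str = "split"
) -> BreakPointCall | None:
    """Decision rules mapping one junction to a break-point call (or None)."""
    params = params or ComplexParams()
    j = junction
    left, right = j.left, j.right
    mol = [j.molecule_id]

    if not j.same_ref:
        a = (left.ref_id, j.inner_left_ref, "L")
        b = (right.ref_id, j.inner_right_ref, "R")
        la, lb = _canonical(a, b)
        pattern = "AB" if la[0] == left.ref_id else "BA"
        return BreakPointCall(la, lb, "tra_inter_bp", mol, source, pattern=pattern)

    ref = left.ref_id
    if left.orientation != right.orientation:
        lo = min(j.inner_left_ref, j.inner_right_ref)
        hi = max(j.inner_left_ref, j.inner_right_ref)
        return BreakPointCall(
            (ref, lo, "L"), (ref, hi, "R"), "inversion_bp", mol, source,
            pattern=j.orientation_pattern,
        )

    shared = {r for r, _ in left.site_pairs} & {r for r, _ in right.site_pairs}
    if len(shared) >= params.dup_min_overlap:
        unit_lo = max(left.ref_start_bp, right.ref_start_bp)
        unit_hi = min(left.ref_end_bp, right.ref_end_bp)
        if unit_hi > unit_lo:
            full = (
                min(left.ref_start_bp, right.ref_start_bp)
                < unit_lo - params.full_span_margin_bp
                and max(left.ref_end_bp, right.ref_end_bp)
                > unit_hi + params.full_span_margin_bp
            )
            unit = (unit_lo, unit_hi)
            size = unit_hi - unit_lo
            if j.left_qpos and j.right_qpos:
                # the distance between the two copies of a shared site is the
                # unit length; distribute the unlabeled slack symmetrically
                import numpy as _np

                length = float(
                    _np.median(
                        [abs(j.right_qpos[r] - j.left_qpos[r]) for r in shared]
                    )
                )
                if length > size:
                    slack = length - size
                    unit = (unit_lo - slack / 2.0, unit_hi + slack / 2.0)
                    size = length
            return BreakPointCall(
                (ref, unit[0], "L"), (ref, unit[1], "R"), "dup_bp", mol, source,
                unit=unit, size_bp=size, full_span=full,
            )

    direction = 1.0 if left.orientation == "+" else -1.0
    ref_gap = (j.inner_right_ref - j.inner_left_ref) * direction
    delta = ref_gap - j.query_gap_bp
    lo = min(j.inner_left_ref, j.inner_right_ref)
    hi = max(j.inner_left_ref, j.inner_right_ref)
    loci = ((ref, lo, "L"), (ref, hi, "R"))
    if ref_gap < 0:
        # right segment maps upstream of the left one (re-ordered segments)
        if -ref_gap >= params.tra_intra_min_bp:
            return BreakPointCall(*loci, "tra_intra_bp", mol, source)
        return None
    if delta > params.indel_handoff_bp:
        if delta >= params.tra_intra_min_bp:
            return BreakPointCall(*loci, "tra_intra_bp", mol, source)
        return BreakPointCall(*loci, "large_del_bp", mol, source, size_bp=delta)
    if -delta > params.indel_handoff_bp:
        return BreakPointCall(*loci, "large_ins_bp", mol, source, size_bp=-delta)
    return None


def _full_span_records(
    split_set: SplitAlignmentSet,
    calls: list[BreakPointCall],
    params: ComplexParams,
    source: str,
) -> list[FullSpanRecord]:
    out = []
    segs = split_set.segments
    for s1, s2, s3 in zip(segs, segs[1:], segs[2:]):
        if s1.ref_id == s3.ref_id != s2.ref_id:
            out.append(
                FullSpanRecord(
                    "translocation_inter",
                    s1.ref_id,
                    [
                        (s1.ref_id, s1.ref_end_bp if s1.orientation == "+" else s1.ref_start_bp),
                        (s3.ref_id, s3.ref_start_bp if s3.orientation == "+" else s3.ref_end_bp),
                    ],
                    split_set.query_id,
                    source,
                )
            )
        elif s1.ref_id == s2.ref_id == s3.ref_id:
            if s1.orientation == s3.orientation != s2.orientation:
                out.append(
                    FullSpanRecord(
                        "inversion",
                        s1.ref_id,
                        [(s2.ref_id, s2.ref_start_bp), (s2.ref_id, s2.ref_end_bp)],
                        split_set.query_id,
                        source,
                    )
                )
            else:
                gap_12 = abs(s2.ref_start_bp - s1.ref_end_bp)
                gap_23 = abs(s3.ref_start_bp - s2.ref_end_bp)
                if min(gap_12, gap_23) > params.tra_intra_min_bp:
                    out.append(
                        FullSpanRecord(
                            "translocation_intra",
                            s1.ref_id,
                            [(s2.ref_id, s2.ref_start_bp), (s2.ref_id, s2.ref_end_bp)],
                            split_set.query_id,
                            source,
                        )
                    )
    return out


def call_from_split_sets(
    split_sets: list[SplitAlignmentSet],
    params: ComplexParams | None = None,
    molecules=None,
) -> tuple[list[BreakPointCall], list[FullSpanRecord]]:
    """Classify every junction of every molecule; collect full-span evidence."""
    params = params or ComplexParams()
    calls: list[BreakPointCall] = []
    fulls: list[FullSpanRecord] = []
    for ss in split_sets:
        if len(ss.segments) < 2:
            continue
        pos = None
        if molecules is not None and ss.query_id in molecules:
            pos = molecules[ss.query_id].positions
        mol_calls = [
            c
            for jn in make_junctions(ss, params, molecule_positions=pos)
            if (c := classify_junction(jn, params)) is not None
        ]
        calls.extend(mol_calls)
        fulls.extend(_full_span_records(ss, mol_calls, params, "split"))
    return calls, fulls


def call_from_contigs(
    contig_alignments: list[AlignmentRecord], params: ComplexParams | None = None
) -> tuple[list[BreakPointCall], list[FullSpanRecord]]:
    """Same junction logic applied to contig-to-reference alignments.

    Contigs give long-range evidence (translocations especially); support is
    counted once per contig and tagged ``source='contig'``.
    """
    from ..formats.maps import group_split_sets

    params = params or ComplexParams()
    calls: list[BreakPointCall] = []
    fulls: list[FullSpanRecord] = []
    for ss in group_split_sets(contig_alignments):
        if len(ss.segments) < 2:
            continue
        for jn in make_junctions(ss, params):
            c = classify_junction(jn, params, source="contig")
            if c is not None:
                calls.append(c)
        fulls.extend(_full_span_records(ss, calls, params, "contig"))
    return calls, fulls
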