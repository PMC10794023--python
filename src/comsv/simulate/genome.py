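"""Derived-genome construction: apply SV events to reference label maps.

A derived chromosome is represented as an ordered list of :class:`Piece`s —
literal reference spans (possibly reversed) and novel inserted material.
Materializing the pieces yields the haplotype label map together with a
liftover table mapping every output label back to its source reference label
(or marking it novel).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..formats.maps import LabelMap
from .events import CloneGraph, SVEvent

__all__ = [
    "Piece",
    "Liftover",
    "HaplotypeGenome",
    "build_chromosome_pieces",
    "materialize_pieces",
    "apply_svs_to_map",
    "build_haplotype_genome",
    "build_clone_genomes",
    "project_position",
]


@dataclass
class Piece:
    kind: str  # 'ref' | 'novel'
    src_ref_id: str | None
    start: float  # ref span [start, end) for 'ref' pieces
    end: float
    strand: int = 1
    novel_offsets: np.ndarray | None = None
    origin_sv: str | None = None
    offset: float = 0.0  # derived-coordinate start, filled during build

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class Liftover:
    """Per-label provenance for one derived map (parallel arrays)."""

    out_pos: np.ndarray
    src_ref: np.ndarray  # object array of ref ids ('' for novel)
    src_pos: np.ndarray  # nan for novel labels
    src_site: np.ndarray  # 1-based ref site index, -1 for novel
    strand: np.ndarray  # +1 / -1
    piece_idx: np.ndarray


@dataclass
class HaplotypeGenome:
    clone: str
    hap: int
    maps: dict[str, LabelMap]
    pieces: dict[str, list[Piece]]
    lifts: dict[str, Liftover]
    boundaries: dict[str, dict[str, list[float]]]  # chrom -> sv_id -> derived offsets
    sv_ids: set[str] = field(default_factory=set)

    @property
    def total_length(self) -> float:
        return sum(m.length_bp for m in self.maps.values())


def _check_non_overlapping(spans: list[tuple[float, float, str]], ref_id: str) -> None:
    spans = sorted(spans)
    for (a0, a1, ida), (b0, b1, idb) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(
                f"overlapping SVs on {ref_id}: {ida} [{a0:.0f},{a1:.0f}) and "
                f"{idb} [{b0:.0f},{b1:.0f})"
            )


def build_chromosome_pieces(
    ref_id: str, ref_len: float, svs: list[SVEvent]
) -> tuple[list[Piece], dict[str, list[float]], float]:
    """Turn the SVs touching one chromosome into an ordered piece list.

    Returns ``(pieces, boundaries, derived_length)`` where ``boundaries`` maps
    each sv_id to the derived coordinates of the junctions it creates.
    """
    span_ops: list[tuple[float, float, str, SVEvent]] = []
    point_ops: dict[float, list[tuple[Piece, SVEvent]]] = {}
    tail_swap: tuple[float, str, float, SVEvent] | None = None

    for sv in svs:
        if sv.sv_type == "translocation_inter":
            if sv.ref_id == ref_id:
                swap = (sv.start_bp, sv.dest_ref_id, sv.dest_bp, sv)
            elif sv.dest_ref_id == ref_id:
                swap = (sv.dest_bp, sv.ref_id, sv.start_bp, sv)
            else:
                continue
            if tail_swap is not None:
                raise ValueError(f"{ref_id}: more than one tail swap on a chromosome")
            tail_swap = swap
            continue
        if sv.ref_id != ref_id:
            continue
        if sv.sv_type == "insertion":
            if sv.novel_label_offsets is None:
                raise ValueError(f"{sv.sv_id}: insertion without a novel label pattern")
            piece = Piece(
                "novel", None, 0.0, sv.size_bp,
                novel_offsets=np.asarray(sv.novel_label_offsets, dtype=float),
                origin_sv=sv.sv_id,
            )
            point_ops.setdefault(sv.start_bp, []).append((piece, sv))
        elif sv.sv_type == "deletion":
            span_ops.append((sv.start_bp, sv.end_bp, "del", sv))
        elif sv.sv_type == "inversion":
            span_ops.append((sv.start_bp, sv.end_bp, "inv", sv))
        elif sv.sv_type == "duplication":
            span_ops.append((sv.start_bp, sv.end_bp, "dup", sv))
        elif sv.sv_type == "translocation_intra":
            span_ops.append((sv.start_bp, sv.end_bp, "cut", sv))
            piece = Piece("ref", ref_id, sv.start_bp, sv.end_bp, origin_sv=sv.sv_id)
            point_ops.setdefault(sv.dest_bp, []).append((piece, sv))

    limit = tail_swap[0] if tail_swap is not None else ref_len
    for s, e, _, sv in span_ops:
        if s < 0 or e > ref_len:
            raise ValueError(f"{sv.sv_id}: span [{s:.0f},{e:.0f}) exceeds map {ref_id}")
        if e > limit:
            raise ValueError(f"{sv.sv_id}: SV extends into a swapped tail on {ref_id}")
    for p in point_ops:
        if p > limit:
            raise ValueError(f"insertion point {p:.0f} beyond tail swap on {ref_id}")
    _check_non_overlapping(
        [(s, e, sv.sv_id) for s, e, _, sv in span_ops]
        + [(p, p, f"point@{p:.0f}") for p in point_ops],
        ref_id,
    )
    for p in point_ops:
        for s, e, _, sv in span_ops:
            if s < p < e:
                raise ValueError(f"insertion point {p:.0f} inside span of {sv.sv_id}")

    pieces: list[Piece] = []
    boundaries: dict[str, list[float]] = {}
    offset = 0.0

    def emit(piece: Piece) -> None:
        nonlocal offset
        piece.offset = offset
        offset += piece.length
        pieces.append(piece)

    events = sorted(
        [(s, 0, ("span", s, e, kind, sv)) for s, e, kind, sv in span_ops]
        + [(p, 1, ("point", p, None, None, None)) for p in point_ops]
    )
    cursor = 0.0
    for pos, _, (etype, s, e, kind, sv) in events:
        if pos > cursor:
            emit(Piece("ref", ref_id, cursor, pos))
        if etype == "point":
            for piece, psv in point_ops[pos]:
                if psv.sv_type == "translocation_intra":
                    boundaries.setdefault(psv.sv_id, []).extend(
                        [offset, offset + piece.length]
                    )
                else:
                    boundaries.setdefault(psv.sv_id, []).extend(
                        [offset, offset + piece.length]
                    )
                emit(piece)
            cursor = max(cursor, pos)
        else:
            if kind == "del":
                boundaries.setdefault(sv.sv_id, []).append(offset)
            elif kind == "inv":
                boundaries.setdefault(sv.sv_id, []).extend([offset, offset + (e - s)])
                emit(Piece("ref", ref_id, s, e, strand=-1, origin_sv=sv.sv_id))
            elif kind == "dup":
                emit(Piece("ref", ref_id, s, e))
                boundaries.setdefault(sv.sv_id, []).append(offset)
                emit(Piece("ref", ref_id, s, e, origin_sv=sv.sv_id))
            elif kind == "cut":
                boundaries.setdefault(sv.sv_id, []).insert(0, offset)
            cursor = e
    if limit > cursor:
        emit(Piece("ref", ref_id, cursor, limit))
    if tail_swap is not None:
        pos, other_ref, other_pos, sv = tail_swap
        boundaries.setdefault(sv.sv_id, []).append(offset)
        # swapped-in tail length needs the partner chromosome's length; the
        # piece end is patched by the caller via ``other_len``
        emit(Piece("ref", other_ref, other_pos, np.inf, origin_sv=sv.sv_id))
    return pieces, boundaries, offset


def materialize_pieces(
    pieces: list[Piece], ref_maps: dict[str, LabelMap], map_id: str
) -> tuple[LabelMap, Liftover]:
    """Build the derived label map and liftover from a piece list."""
    outs, refs, spos, ssite, strands, pidx = [], [], [], [], [], []
    total = 0.0
    for k, pc in enumerate(pieces):
        if np.isinf(pc.end):  # tail piece: extend to the end of the source map
            pc.end = ref_maps[pc.src_ref_id].length_bp
        if pc.kind == "ref":
            rm = ref_maps[pc.src_ref_id]
            i0 = int(np.searchsorted(rm.positions, pc.start, side="left"))
            i1 = int(np.searchsorted(rm.positions, pc.end, side="left"))
            p = rm.positions[i0:i1]
            sites = np.arange(i0 + 1, i1 + 1)
            if pc.strand > 0:
                out = pc.offset + (p - pc.start)
            else:
                out = pc.offset + (pc.end - p)
                out, p, sites = out[::-1], p[::-1], sites[::-1]
            outs.append(out)
            refs.append(np.full(p.size, pc.src_ref_id, dtype=object))
            spos.append(p)
            ssite.append(sites)
            strands.append(np.full(p.size, pc.strand, dtype=int))
            pidx.append(np.full(p.size, k, dtype=int))
        else:
            off = np.sort(np.asarray(pc.novel_offsets, dtype=float))
            off = off[(off > 0) & (off <= pc.length)]
            outs.append(pc.offset + off)
            refs.append(np.full(off.size, "", dtype=object))
            spos.append(np.full(off.size, np.nan))
            ssite.append(np.full(off.size, -1, dtype=int))
            strands.append(np.ones(off.size, dtype=int))
            pidx.append(np.full(off.size, k, dtype=int))
        total = pc.offset + pc.length
    if outs:
        out_pos = np.concatenate(outs)
        lift = Liftover(
            out_pos,
            np.concatenate(refs),
            np.concatenate(spos),
            np.concatenate(ssite),
            np.concatenate(strands),
            np.concatenate(pidx),
        )
    else:
        lift = Liftover(*(np.empty(0),) * 6)
        out_pos = lift.out_pos
    # guard against boundary-coincident labels (measure-zero duplicates)
    if out_pos.size:
        keep = np.concatenate([[out_pos[0] > 0], np.diff(out_pos) > 1e-9])
        if not np.all(keep):
            lift = Liftover(*(a[keep] for a in (
                lift.out_pos, lift.src_ref, lift.src_pos, lift.src_site,
                lift.strand, lift.piece_idx,
            )))
            out_pos = lift.out_pos
    derived = LabelMap(map_id, total, out_pos)
    return derived, lift


def apply_svs_to_map(
    ref_map: LabelMap, svs: list[SVEvent]
) -> tuple[LabelMap, Liftover]:
    """Apply intra-chromosomal SVs to one reference map.

    Returns the haplotype map and a liftover table mapping each output label
    to its source reference label (``src_site == -1`` marks novel labels).
    """
    if any(sv.sv_type == "translocation_inter" for sv in svs):
        raise ValueError("inter translocations need the genome-level builder")
    pieces, _, _ = build_chromosome_pieces(ref_map.map_id, ref_map.length_bp, svs)
    return materialize_pieces(pieces, {ref_map.map_id: ref_map}, ref_map.map_id)


def build_haplotype_genome(
    ref_maps: dict[str, LabelMap], clone: str, hap: int, svs: list[SVEvent]
) -> HaplotypeGenome:
    applicable = [sv for sv in svs if hap in sv.haplotypes()]
    maps: dict[str, LabelMap] = {}
    pieces: dict[str, list[Piece]] = {}
    lifts: dict[str, Liftover] = {}
    boundaries: dict[str, dict[str, list[float]]] = {}
    for ref_id, rm in ref_maps.items():
        pcs, bnd, _ = build_chromosome_pieces(ref_id, rm.length_bp, applicable)
        derived, lift = materialize_pieces(pcs, ref_maps, ref_id)
        maps[ref_id] = derived
        pieces[ref_id] = pcs
        lifts[ref_id] = lift
        boundaries[ref_id] = bnd
    return HaplotypeGenome(
        clone, hap, maps, pieces, lifts, boundaries,
        sv_ids={sv.sv_id for sv in applicable},
    )


def build_clone_genomes(
    ref_maps: dict[str, LabelMap], graph: CloneGraph, diploid: bool = True
) -> dict[tuple[str, int], HaplotypeGenome]:
    """Materialize every clone's haplotypes along the evolution graph."""
    haps = (0, 1) if diploid else (0,)
    genomes: dict[tuple[str, int], HaplotypeGenome] = {}
    for clone in graph.clones:
        svs = graph.sv_set(clone)
        for hap in haps:
            genomes[(clone, hap)] = build_haplotype_genome(ref_maps, clone, hap, svs)
    return genomes


def project_position(
    pieces: list[Piece], ref_id: str, pos: float
) -> float | None:
    """Map a reference coordinate to derived coordinates (None if deleted)."""
    for pc in pieces:
        if pc.kind != "ref" or pc.src_ref_id != ref_id:
            continue
        if pc.start <= pos < pc.end:
            if pc.strand > 0:
                return pc.offset + (pos - pc.start)
            return pc.offset + (pc.end - pos)
    return None
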