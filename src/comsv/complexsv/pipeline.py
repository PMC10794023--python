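"""Complex-SV pipeline orchestration: split alignments, optional targeted
re-alignment of partially aligned molecules, contig evidence, consolidation.
"""
from __future__ import annotations

import logging

from ..align.fit import ScoringParams, detect_tandem_dup_by_realign
from ..calls import SVCall
from ..formats.maps import AlignmentRecord, LabelMap, group_split_sets
from .consolidate import ComplexSVCall, consolidate_breakpoints
from .junctions import BreakPointCall, ComplexParams, call_from_contigs, call_from_split_sets

logger = logging.getLogger(__name__)

__all__ = ["call_complex_svs", "complex_calls_to_svcalls"]


def complex_calls_to_svcalls(calls: list[ComplexSVCall]) -> list[SVCall]:
    out = []
    for i, c in enumerate(calls):
        support = max([*c.support_by_breakpoint, 0]) if c.support_by_breakpoint else 0
        out.append(
            SVCall(
                call_id=f"complex_{i}",
                sv_type=c.sv_type,
                ref_id=c.ref_id,
                start_bp=c.start_bp,
                end_bp=c.end_bp,
                size_bp=c.size_bp,
                allele_fraction=float("nan"),
                support=len(c.supporting_molecules) or support,
                total=len(c.supporting_molecules) or support,
                status=c.status,
                confidence=c.confidence,
                source="complex",
                ref_id_b=c.ref_id_b,
                pos_b=c.pos_b,
                supporting_molecules=c.supporting_molecules,
            )
        )
    return out


def call_complex_svs(
    alignment_records: list[AlignmentRecord],
    molecules: dict[str, LabelMap],
    ref_maps: dict[str, LabelMap],
    params: ComplexParams | None = None,
    contig_alignments: list[AlignmentRecord] | None = None,
    realign: bool = True,
    scoring: ScoringParams | None = None,
) -> tuple[list[SVCall], list[SVCall], dict]:
    """Run the complex pipeline.

    Returns ``(complex_calls, junction_indels, stats)``; junction-implied
    indels are handed to the annotation step, not reported as complex SVs.
    """
    params = params or ComplexParams()
    lengths = {m.map_id: m.length_bp for m in molecules.values()}
    split_sets = group_split_sets(
        alignment_records, query_lengths=lengths,
        overlap_slack_bp=params.query_overlap_slack_bp,
    )
    bp_calls, full_span = call_from_split_sets(split_sets, params, molecules=molecules)
    stats = {
        "split_sets": sum(1 for s in split_sets if len(s.segments) > 1),
        "junction_calls": len(bp_calls),
        "full_span_records": len(full_span),
    }

    if realign:
        realign_hits = 0
        for ss in split_sets:
            if len(ss.segments) != 1 or not ss.unaligned_intervals:
                continue
            mol = molecules.get(ss.query_id)
            ref = ref_maps.get(ss.segments[0].ref_id)
            if mol is None or ref is None:
                continue
            ev = detect_tandem_dup_by_realign(ss, mol, ref, scoring)
            if ev is not None:
                realign_hits += 1
                bp_calls.append(
                    BreakPointCall(
                        locus_a=(ev.ref_id, ev.unit_start_bp, "L"),
                        locus_b=(ev.ref_id, ev.unit_end_bp, "R"),
                        inferred_type="dup_bp",
                        support=[ev.molecule_id],
                        source="realign",
                        unit=(ev.unit_start_bp, ev.unit_end_bp),
                    )
                )
        stats["realign_dup_evidence"] = realign_hits

    if contig_alignments:
        ctg_calls, ctg_full = call_from_contigs(contig_alignments, params)
        bp_calls.extend(ctg_calls)
        full_span.extend(ctg_full)
        stats["contig_junction_calls"] = len(ctg_calls)

    complex_calls, junction_indels = consolidate_breakpoints(bp_calls, full_span, params)
    stats["complex_calls"] = len(complex_calls)
    stats["junction_indels"] = len(junction_indels)
    logger.info("complex pipeline: %s", stats)
    return complex_calls_to_svcalls(complex_calls), junction_indels, stats
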