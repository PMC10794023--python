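"""Cross-pipeline annotation and de-duplication of the final call set.

Redundancy rules: an insertion whose enclosing region overlaps a duplication
of compatible size is reported once, as the duplication; junction-implied
indels that duplicate an indel-pipeline call are folded into it; deletions
coinciding with a translocation's excised span are subsumed by the
translocation.  Optionally attaches overlapping gene names (half-open
interval overlap) from a BED-style gene list.
"""
from __future__ import annotations

from dataclasses import dataclass

from ..calls import SVCall
from .junctions import ComplexParams

__all__ = ["GeneInterval", "annotate_and_deduplicate", "find_cross_pipeline_duplicates"]


@dataclass(frozen=True)
class GeneInterval:
    name: str
    ref_id: str
    start_bp: float
    end_bp: float  # half-open


def _interval(call: SVCall) -> tuple[float, float]:
    if call.region_start_bp is not None and call.region_end_bp is not None:
        return call.region_start_bp, call.region_end_bp
    lo, hi = call.start_bp, call.end_bp
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def _overlap(a: SVCall, b: SVCall, pad: float = 0.0) -> bool:
    if a.ref_id != b.ref_id:
        return False
    a0, a1 = _interval(a)
    b0, b1 = _interval(b)
    return a0 - pad < b1 and b0 - pad < a1


def _reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    a0, a1 = _interval(a)
    b0, b1 = _interval(b)
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / max(a1 - a0, 1e-9), ov / max(b1 - b0, 1e-9))


def find_cross_pipeline_duplicates(calls: list[SVCall]) -> list[tuple[str, str]]:
    """Pairs of same-type calls from different sources covering one locus.

    Used as a post-condition: after de-duplication this must be empty.
    """
    dups = []
    for i, a in enumerate(calls):
        for b in calls[i + 1:]:
            if a.sv_type != b.sv_type or a.source == b.source:
                continue
            if _reciprocal_overlap(a, b) >= 0.5 or (
                a.sv_type == "insertion" and _overlap(a, b, pad=10_000.0)
            ):
                dups.append((a.call_id, b.call_id))
    return dups


def annotate_and_deduplicate(
    complex_calls: list[SVCall],
    indel_calls: list[SVCall],
    genes: list[GeneInterval] | None = None,
    params: ComplexParams | None = None,
) -> list[SVCall]:
    """Produce the unified annotated call set (see module docstring)."""
    params = params or ComplexParams()
    complex_calls = list(complex_calls)
    indel_calls = list(indel_calls)
    suppressed: dict[str, str] = {}

    dups = [c for c in complex_calls if c.sv_type == "duplication"]
    tras = [c for c in complex_calls if c.sv_type.startswith("translocation")]

    kept_indels: list[SVCall] = []
    for call in indel_calls:
        drop = False
        if call.sv_type == "insertion":
            for d in dups:
                size_ok = (
                    abs(call.size_bp - d.size_bp)
                    <= params.dedup_size_tol_frac * max(d.size_bp, 1.0)
                )
                if size_ok and _overlap(call, d, pad=params.merge_window_bp):
                    suppressed[call.call_id] = d.call_id
                    d.support = max(d.support, d.support + call.support)
                    drop = True
                    break
        if not drop and call.sv_type == "deletion":
            for t in tras:
                if call.ref_id == t.ref_id and _overlap(call, t, pad=params.merge_window_bp):
                    suppressed[call.call_id] = t.call_id
                    drop = True
                    break
        if not drop:
            kept_indels.append(call)

    # fold junction-implied indels into indel-pipeline calls covering them
    pipeline = [c for c in kept_indels if c.source == "indel"]
    final_indels: list[SVCall] = []
    for call in kept_indels:
        if call.source == "complex-junction":
            twin = next(
                (
                    p for p in pipeline
                    if p.sv_type == call.sv_type and _reciprocal_overlap(p, call) >= 0.5
                ),
                None,
            )
            if twin is not None:
                twin.supporting_molecules = sorted(
                    set(twin.supporting_molecules) | set(call.supporting_molecules)
                )
                twin.support = len(twin.supporting_molecules)
                suppressed[call.call_id] = twin.call_id
                continue
        final_indels.append(call)

    out = final_indels + complex_calls
    for call in out:
        if call.call_id in suppressed:
            call.cross_ref = suppressed[call.call_id]
    if genes:
        by_ref: dict[str, list[GeneInterval]] = {}
        for g in genes:
            by_ref.setdefault(g.ref_id, []).append(g)
        for call in out:
            lo, hi = _interval(call)
            call.genes = sorted(
                g.name for g in by_ref.get(call.ref_id, [])
                if g.start_bp < hi and lo < g.end_bp
            )
    out.sort(key=lambda c: (c.ref_id, c.start_bp, c.sv_type))
    return out
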