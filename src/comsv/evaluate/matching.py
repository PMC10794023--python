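"""Match SV calls against simulator truth and compute benchmark metrics.

Matching is greedy by ascending break-point distance and strictly
one-to-one.  Span types (inversion, duplication, intra translocation) also
require a minimum reciprocal overlap; indels are point+size events matched
by locus distance and size agreement (their enclosing regions are label-
resolution, so reciprocal overlap of the region would punish small events);
translocations are matched on both break points, ignoring span.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..calls import SVCall
from ..simulate.events import TruthRecord

__all__ = ["MatchCriteria", "MatchResult", "match_calls", "precision_recall_f1",
           "stratify_by_stage"]

_SPAN_TYPES = ("inversion", "duplication", "translocation_intra")


@dataclass
class MatchCriteria:
    breakpoint_tolerance_bp: float = 10_000.0
    min_reciprocal_overlap: float = 0.5
    require_type_match: bool = True
    require_zygosity_match: bool = False
    min_size_ratio: float = 0.5  # indel size agreement (smaller/larger)

    def __post_init__(self) -> None:
        if self.breakpoint_tolerance_bp < 0:
            raise ValueError("tolerance must be >= 0")
        if not 0 < self.min_reciprocal_overlap <= 1:
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")


@dataclass
class MatchResult:
    true_positives: list[tuple[SVCall, TruthRecord]]
    false_positives: list[SVCall]
    false_negatives: list[TruthRecord]

    @property
    def tp(self) -> int:
        return len(self.true_positives)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


def _truth_interval(t: TruthRecord) -> tuple[float, float]:
    return t.start_bp, max(t.end_bp, t.start_bp + 1.0)


def _zygosity_matches(call: SVCall, t: TruthRecord) -> bool:
    return call.zygosity == t.sv.zygosity


def _pair_distance(call: SVCall, t: TruthRecord, criteria: MatchCriteria) -> float | None:
    """Break-point distance if the pair is matchable under the criteria."""
    if criteria.require_type_match and call.sv_type != t.sv.sv_type:
        return None
    tol = criteria.breakpoint_tolerance_bp
    if call.sv_type.startswith("translocation") and t.sv.sv_type.startswith("translocation"):
        if call.sv_type == "translocation_inter":
            # compare the two (ref, pos) loci order-independently
            call_loci = sorted(
                [(call.ref_id, call.start_bp), (call.ref_id_b or "", call.pos_b or 0.0)]
            )
            truth_loci = sorted(
                [(t.ref_id, t.sv.start_bp), (t.sv.dest_ref_id or "", t.sv.dest_bp or 0.0)]
            )
            if [r for r, _ in call_loci] != [r for r, _ in truth_loci]:
                return None
            d1 = abs(call_loci[0][1] - truth_loci[0][1])
            d2 = abs(call_loci[1][1] - truth_loci[1][1])
        else:
            if call.ref_id != t.ref_id:
                return None
            # an intra translocation has three break points (span ends and
            # destination); the call reports the outermost junction loci
            pts_call = sorted([call.start_bp, call.end_bp])
            truth_pts = [t.sv.start_bp, t.sv.end_bp]
            if t.sv.dest_bp is not None:
                truth_pts.append(t.sv.dest_bp)
            truth_pts.sort()
            d1 = abs(pts_call[0] - truth_pts[0])
            d2 = abs(pts_call[1] - truth_pts[-1])
        if d1 <= tol and d2 <= tol:
            dist = d1 + d2
        else:
            return None
    elif call.sv_type in _SPAN_TYPES:
        if call.ref_id != t.ref_id:
            return None
        t0, t1 = _truth_interval(t)
        ov = min(call.end_bp, t1) - max(call.start_bp, t0)
        if ov <= 0:
            return None
        rec = min(ov / (call.end_bp - call.start_bp), ov / (t1 - t0))
        if rec < criteria.min_reciprocal_overlap:
            return None
        d1 = abs(call.start_bp - t0)
        d2 = abs(call.end_bp - t1)
        if d1 > tol or d2 > tol:
            return None
        dist = d1 + d2
    else:  # indels: locus distance + size agreement
        if call.ref_id != t.ref_id:
            return None
        center_t = 0.5 * (t.start_bp + t.end_bp)
        if call.region_start_bp is not None and call.region_end_bp is not None:
            lo, hi = call.region_start_bp, call.region_end_bp
            in_region = lo - tol <= center_t <= hi + tol
        else:
            in_region = abs(0.5 * (call.start_bp + call.end_bp) - center_t) <= tol
        if not in_region:
            return None
        if t.sv.size_bp > 0 and call.size_bp > 0:
            ratio = min(call.size_bp, t.sv.size_bp) / max(call.size_bp, t.sv.size_bp)
            if ratio < criteria.min_size_ratio:
                return None
        dist = abs(0.5 * (call.start_bp + call.end_bp) - center_t)
    if criteria.require_zygosity_match and not _zygosity_matches(call, t):
        return None
    return dist


def match_calls(
    calls: list[SVCall],
    truth: list[TruthRecord],
    criteria: MatchCriteria | None = None,
) -> MatchResult:
    """Greedy one-to-one matching by ascending break-point distance."""
    criteria = criteria or MatchCriteria()
    edges = []
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truth):
            d = _pair_distance(call, t, criteria)
            if d is not None:
                edges.append((d, ci, ti))
    edges.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    tps = []
    for d, ci, ti in edges:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        tps.append((calls[ci], truth[ti]))
    fps = [c for i, c in enumerate(calls) if i not in used_c]
    fns = [t for i, t in enumerate(truth) if i not in used_t]
    return MatchResult(tps, fps, fns)


def precision_recall_f1(tp: int, fp: int, fn: int) -> dict[str, float | None]:
    """Precision/recall/F1 with honest None (not 0) for empty denominators."""
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}


def stratify_by_stage(result: MatchResult) -> dict[str, dict]:
    """Per-origin-clone recall (false positives cannot be attributed to a

    stage, so stratified precision is reported as None)."""
    stages: dict[str, dict[str, int]] = {}
    for _, t in result.true_positives:
        stages.setdefault(t.origin_clone, {"tp": 0, "fn": 0})["tp"] += 1
    for t in result.false_negatives:
        stages.setdefault(t.origin_clone, {"tp": 0, "fn": 0})["fn"] += 1
    out = {}
    for stage, counts in sorted(stages.items()):
        tp, fn = counts["tp"], counts["fn"]
        out[stage] = {
            "recall": tp / (tp + fn) if (tp + fn) > 0 else None,
            "precision": None,
            "tp": tp,
            "fn": fn,
        }
    return out
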