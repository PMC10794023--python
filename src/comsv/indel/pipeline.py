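"""End-to-end indel pipeline orchestration.

normalize -> arbitrate -> candidate regions -> cluster -> call -> post-process
"""
from __future__ import annotations

import logging

from ..formats.maps import AlignmentRecord, LabelMap
from ..calls import SVCall
from .arbitrate import arbitrate_abnormal_pairs
from .calling import call_indel, postprocess_calls
from .cluster import cluster_distances
from .observations import normalize_alignment, observations_frame
from .params import IndelParams
from .regions import build_candidate_regions

logger = logging.getLogger(__name__)

__all__ = ["call_indels"]


def call_indels(
    alignment_records: list[AlignmentRecord],
    molecules: dict[str, LabelMap],
    ref_maps: dict[str, LabelMap],
    params: IndelParams | None = None,
) -> tuple[list[SVCall], dict]:
    """Run the full indel pipeline; returns (calls, per-step statistics)."""
    params = params or IndelParams()
    normalized = []
    for rec in alignment_records:
        mol = molecules.get(rec.query_id)
        if mol is None or rec.ref_id not in ref_maps:
            continue
        normalized.append(normalize_alignment(rec, mol, ref_maps[rec.ref_id], params))
    df = observations_frame(normalized)
    df = arbitrate_abnormal_pairs(df, normalized, params)
    stats = {
        "alignments": len(normalized),
        "observations": int(len(df)),
        "abnormal": int(df["abnormal"].sum()) if len(df) else 0,
        "candidates": int((df["verdict"] == "candidate").sum()) if len(df) else 0,
        "corrected": int((df["verdict"] == "corrected").sum()) if len(df) else 0,
        "discarded_alignments": sum(na.discarded for na in normalized),
    }
    regions = build_candidate_regions(df, normalized, ref_maps, params)
    stats["regions"] = len(regions)
    raw = []
    for region in regions:
        clustering = cluster_distances(region.distances, params)
        call = call_indel(region, clustering, params)
        if call is not None:
            confs = {
                na.molecule_id: na.record.confidence for na in normalized
            }
            sup_conf = [confs.get(m, 15.0) for m in call.supporting_molecules]
            if sup_conf:
                call.mean_alignment_confidence = float(sum(sup_conf) / len(sup_conf))
            raw.append(call)
    stats["raw_calls"] = len(raw)
    calls = postprocess_calls(raw, params)
    stats["calls"] = len(calls)
    logger.info("indel pipeline: %s", stats)
    return calls, stats
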