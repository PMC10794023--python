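"""Turn clustered candidate regions into typed, scored indel calls."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..calls import SVCall
from .cluster import DistanceClustering
from .params import IndelParams
from .regions import CandidateRegion

__all__ = ["IndelCall", "call_indel", "postprocess_calls"]


@dataclass
class IndelCall:
    sv_type: str  # insertion | deletion
    zygosity: str  # het | hom | multi-allelic | unknown
    ref_id: str
    region_start_bp: float
    region_end_bp: float
    size_estimate_bp: float
    support: int
    total: int
    allele_fraction: float
    expected_bp: float
    variant_mean_bp: float
    cluster_separation: float  # separation / pooled sd, for scoring
    mean_alignment_confidence: float = 15.0
    supporting_molecules: list[str] = field(default_factory=list)
    confidence: float = 0.0

    @property
    def center_bp(self) -> float:
        return 0.5 * (self.region_start_bp + self.region_end_bp)

    @property
    def start_bp(self) -> float:
        if self.sv_type == "insertion":
            return self.center_bp
        return self.center_bp - self.size_estimate_bp / 2.0

    @property
    def end_bp(self) -> float:
        if self.sv_type == "insertion":
            return self.center_bp
        return self.center_bp + self.size_estimate_bp / 2.0


def call_indel(
    region: CandidateRegion,
    clustering: DistanceClustering,
    params: IndelParams | None = None,
) -> IndelCall | None:
    """Apply the typing/zygosity rules to one region's clustering.

    A cluster is a variant cluster when its mean deviates from the expected
    anchor distance by at least the minimum indel size; insertion if larger,
    deletion if smaller.  Zygosity follows the cluster layout; allele
    fraction is always reported from cluster sizes (mixtures make fixed
    het/hom fractions meaningless).
    """
    params = params or IndelParams()
    expected = region.expected_bp
    variant = [
        c for c in clustering.clusters
        if abs(c.mean_bp - expected) >= params.min_indel_size_bp
    ]
    reference_like = [
        c for c in clustering.clusters
        if abs(c.mean_bp - expected) < params.min_indel_size_bp
    ]
    if not variant:
        return None
    primary = max(variant, key=lambda c: (c.n, -abs(c.mean_bp - expected)))
    total = sum(c.n for c in clustering.clusters)
    support = primary.n
    af = support / total
    k = clustering.chosen_k
    if len(variant) >= 2:
        zygosity = "multi-allelic"
    elif reference_like:
        zygosity = "het" if af < params.hom_fraction_threshold else "hom"
    else:  # every molecule shows the shifted distance
        zygosity = "hom" if af >= params.hom_fraction_threshold else "unknown"
    sv_type = "insertion" if primary.mean_bp > expected else "deletion"
    pooled_sd = max(
        np.sqrt(np.mean([max(c.sd_bp, params.sd_floor_bp) ** 2 for c in clustering.clusters])),
        params.sd_floor_bp,
    )
    if reference_like:
        ref_mean = reference_like[0].mean_bp
    else:
        ref_mean = expected
    separation = abs(primary.mean_bp - ref_mean) / pooled_sd
    mol_ids = [region.observations[i][0] for i in primary.members]
    return IndelCall(
        sv_type=sv_type,
        zygosity=zygosity,
        ref_id=region.ref_id,
        region_start_bp=region.anchor_left_bp,
        region_end_bp=region.anchor_right_bp,
        size_estimate_bp=abs(primary.mean_bp - expected),
        support=support,
        total=total,
        allele_fraction=af,
        expected_bp=expected,
        variant_mean_bp=primary.mean_bp,
        cluster_separation=float(separation),
        supporting_molecules=sorted(set(mol_ids)),
    )


def _reciprocal_overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / max(a1 - a0, 1e-9), ov / max(b1 - b0, 1e-9))


def _confidence(call: IndelCall, cov_median: float, params: IndelParams) -> float:
    features = np.array([
        np.log2(max(call.support, 1)),
        call.allele_fraction,
        min(call.cluster_separation, 6.0),
        min(call.mean_alignment_confidence / 20.0, 1.0),
        min(call.total / max(cov_median, 1.0), 2.0),
    ])
    w = np.asarray(params.confidence_weights)
    z = params.confidence_bias + float(w @ features)
    return float(1.0 / (1.0 + np.exp(-z)))


def postprocess_calls(
    raw_calls: list[IndelCall],
    params: IndelParams | None = None,
) -> list[SVCall]:
    """Merge redundant calls, score them and emit filtered :class:`SVCall`s.

    Calls of the same type whose enclosing regions reciprocally overlap by at
    least ``merge_overlap_frac`` are merged into a support-weighted consensus.
    Confidence is a logistic score over support, allele fraction, cluster
    separation, alignment confidence and relative local coverage; calls below
    ``report_threshold`` are dropped.
    """
    params = params or IndelParams()
    calls = sorted(raw_calls, key=lambda c: (c.ref_id, c.region_start_bp))
    merged: list[IndelCall] = []
    for call in calls:
        target = None
        for prev in merged:
            if prev.sv_type != call.sv_type or prev.ref_id != call.ref_id:
                continue
            if _reciprocal_overlap(
                prev.region_start_bp, prev.region_end_bp,
                call.region_start_bp, call.region_end_bp,
            ) >= params.merge_overlap_frac:
                target = prev
                break
        if target is None:
            merged.append(call)
            continue
        w0, w1 = target.support, call.support
        wt = w0 + w1
        target.region_start_bp = (w0 * target.region_start_bp + w1 * call.region_start_bp) / wt
        target.region_end_bp = (w0 * target.region_end_bp + w1 * call.region_end_bp) / wt
        target.size_estimate_bp = (w0 * target.size_estimate_bp + w1 * call.size_estimate_bp) / wt
        target.variant_mean_bp = (w0 * target.variant_mean_bp + w1 * call.variant_mean_bp) / wt
        target.supporting_molecules = sorted(
            set(target.supporting_molecules) | set(call.supporting_molecules)
        )
        target.support = len(target.supporting_molecules)
        target.total = max(target.total, call.total)
        target.allele_fraction = min(1.0, target.support / max(target.total, 1))
        target.cluster_separation = max(target.cluster_separation, call.cluster_separation)

    cov_median = float(np.median([c.total for c in merged])) if merged else 1.0
    out: list[SVCall] = []
    serial = 0
    for call in merged:
        call.confidence = _confidence(call, cov_median, params)
        if call.confidence < params.report_threshold:
            continue
        if call.support < params.min_support:
            continue
        out.append(
            SVCall(
                call_id=f"indel_{serial}",
                sv_type=call.sv_type,
                ref_id=call.ref_id,
                start_bp=call.start_bp,
                end_bp=call.end_bp,
                size_bp=call.size_estimate_bp,
                zygosity=call.zygosity,
                allele_fraction=call.allele_fraction,
                support=call.support,
                total=call.total,
                status="complete",
                confidence=call.confidence,
                source="indel",
                region_start_bp=call.region_start_bp,
                region_end_bp=call.region_end_bp,
                supporting_molecules=call.supporting_molecules,
            )
        )
        serial += 1
    return out
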