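"""Candidate indel regions: merge overlapping candidate pairs, choose anchor
labels and pool anchor-to-anchor distances across molecules.

Molecules missing the labels nearest a break point still contribute: the
spanning distance is computed between the region anchors, which are chosen
so that most spanning molecules have them matched.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..formats.maps import LabelMap
from .observations import NormalizedAlignment
from .params import IndelParams

__all__ = ["CandidateRegion", "build_candidate_regions"]


@dataclass
class CandidateRegion:
    ref_id: str
    anchor_left_site: int
    anchor_right_site: int
    anchor_left_bp: float
    anchor_right_bp: float
    expected_bp: float
    member_pairs: list[tuple[int, int]]
    observations: list[tuple[str, float]] = field(default_factory=list)  # (mol, dist)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d in self.observations])


def _merge_intervals(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group site-index intervals that overlap or share a site."""
    groups: list[list[tuple[int, int]]] = []
    for ls, rs in sorted(pairs):
        if groups and ls <= max(r for _, r in groups[-1]):
            groups[-1].append((ls, rs))
        else:
            groups.append([(ls, rs)])
    return groups


def build_candidate_regions(
    df: pd.DataFrame,
    alignments: list[NormalizedAlignment],
    ref_maps: dict[str, LabelMap],
    params: IndelParams | None = None,
) -> list[CandidateRegion]:
    """Build candidate regions from arbitration verdicts.

    Each candidate pair belongs to exactly one region.  Spanning distances
    include per-pair corrections applied during arbitration.
    """
    params = params or IndelParams()
    regions: list[CandidateRegion] = []
    if df.empty:
        return regions
    cand = df[df["verdict"] == "candidate"]
    if cand.empty:
        return regions

    # pre-index alignments by ref for spanning lookup
    by_ref: dict[str, list[NormalizedAlignment]] = {}
    for na in alignments:
        if not na.discarded:
            by_ref.setdefault(na.record.ref_id, []).append(na)

    for ref_id in sorted(cand["ref"].unique()):
        ref_map = ref_maps[ref_id]
        pairs = sorted(
            set(
                map(tuple, cand.loc[cand["ref"] == ref_id, ["ls", "rs"]].values.tolist())
            )
        )
        for group in _merge_intervals(pairs):
            lo = min(ls for ls, _ in group)
            hi = max(rs for _, rs in group)
            span_bp = ref_map.positions[hi - 1] - ref_map.positions[lo - 1]
            subgroups = [group]
            if span_bp > params.max_region_bp and len(group) > 1:
                subgroups = _split_region(group, ref_map, params.max_region_bp)
            for sub in subgroups:
                region = _finalize_region(sub, ref_id, ref_map, by_ref.get(ref_id, []), params)
                if region is not None:
                    regions.append(region)
    regions.sort(key=lambda r: (r.ref_id, r.anchor_left_bp))
    return regions


def _split_region(
    group: list[tuple[int, int]], ref_map: LabelMap, max_region_bp: float
) -> list[list[tuple[int, int]]]:
    """Split an oversized merged group at its widest internal gap."""
    group = sorted(group)
    gaps = [
        ref_map.positions[b[0] - 1] - ref_map.positions[a[1] - 1]
        for a, b in zip(group, group[1:])
    ]
    if not gaps:
        return [group]
    cut = int(np.argmax(gaps)) + 1
    left, right = group[:cut], group[cut:]
    out = []
    for part in (left, right):
        lo = min(ls for ls, _ in part)
        hi = max(rs for _, rs in part)
        if ref_map.positions[hi - 1] - ref_map.positions[lo - 1] > max_region_bp and len(part) > 1:
            out.extend(_split_region(part, ref_map, max_region_bp))
        else:
            out.append(part)
    return out


def _finalize_region(
    group: list[tuple[int, int]],
    ref_id: str,
    ref_map: LabelMap,
    alignments: list[NormalizedAlignment],
    params: IndelParams,
) -> CandidateRegion | None:
    lo = min(ls for ls, _ in group)
    hi = max(rs for _, rs in group)
    # potential spanners: alignments whose matched sites flank the region
    spanners = [
        na for na in alignments
        if na.ref_sites[0] <= lo and na.ref_sites[-1] >= hi
    ]
    if not spanners:
        return None

    def pick_anchor(start: int, step: int) -> int:
        for s in (start + k * step for k in range(params.anchor_search_sites + 1)):
            if s < 1 or s > ref_map.n_labels:
                break
            frac = np.mean([s in set(na.ref_sites.tolist()) for na in spanners])
            if frac >= params.anchor_min_frac:
                return s
        return start

    anchor_l = pick_anchor(lo, -1)
    anchor_r = pick_anchor(hi, +1)
    a_l_bp = float(ref_map.positions[anchor_l - 1])
    a_r_bp = float(ref_map.positions[anchor_r - 1])
    expected = a_r_bp - a_l_bp
    region = CandidateRegion(
        ref_id, anchor_l, anchor_r, a_l_bp, a_r_bp, expected, sorted(group)
    )
    for na in alignments:
        sites = na.ref_sites
        il = np.flatnonzero(sites == anchor_l)
        ir = np.flatnonzero(sites == anchor_r)
        if il.size == 0 or ir.size == 0:
            continue
        i0, i1 = int(il[0]), int(ir[0])
        dist = abs(na.q_pos[i1] - na.q_pos[i0])
        for pair_idx, delta in na.corrections.items():
            if i0 <= pair_idx < i1:
                dist += delta
        region.observations.append((na.molecule_id, float(dist)))
    if region.n_observations < params.min_coverage:
        return None
    return region
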