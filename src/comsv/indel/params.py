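"""Tunable thresholds for the indel pipeline (config defaults in one place)."""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["IndelParams"]


@dataclass
class IndelParams:
    # abnormal-distance detection: a pair is abnormal when the deviation
    # exceeds BOTH-combined max(absolute, relative * expected)
    abs_threshold_bp: float = 1_500.0
    rel_threshold: float = 0.12
    # arbitration
    min_support: int = 3           # consistent abnormal molecules for a candidate
    min_normal: int = 3            # normal molecules needed to correct an outlier
    min_coverage: int = 6          # molecules at a locus before any verdict
    magnitude_tol_abs_bp: float = 1_200.0
    magnitude_tol_frac: float = 0.5
    max_abnormal_frac: float = 0.5
    min_pairs_for_discard: int = 4
    # candidate regions
    anchor_min_frac: float = 0.5
    anchor_search_sites: int = 3
    max_region_bp: float = 500_000.0
    # clustering
    min_cluster_size: int = 3
    min_separation_bp: float = 1_500.0
    sd_floor_bp: float = 200.0
    max_k: int = 3
    # calling
    min_indel_size_bp: float = 2_000.0
    hom_fraction_threshold: float = 0.85
    # post-processing
    merge_overlap_frac: float = 0.5
    confidence_weights: tuple[float, ...] = (1.5, 1.0, 0.3, 0.5, 0.25)
    confidence_bias: float = -4.5
    report_threshold: float = 0.5

    def deviation_threshold(self, expected_bp: float) -> float:
        return max(self.abs_threshold_bp, self.rel_threshold * expected_bp)
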