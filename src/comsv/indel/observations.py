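"""Distance normalization and per-pair observation extraction.

Every alignment is first normalized by a robust per-molecule scale factor
(the median observed/expected ratio over its intervals, re-estimated after
excluding abnormal intervals) to undo incomplete linearization.  The result
is one :class:`PairObservation` per pair of consecutively matched reference
sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..formats.maps import AlignmentRecord, LabelMap
from .params import IndelParams

__all__ = ["PairObservation", "NormalizedAlignment", "normalize_alignment",
           "observations_frame"]


@dataclass
class PairObservation:
    """Observed vs expected distance between two matched reference sites."""

    molecule_id: str
    ref_id: str
    ref_left_site: int
    ref_right_site: int
    observed_bp: float  # post-normalization
    expected_bp: float

    @property
    def ratio(self) -> float:
        return self.observed_bp / self.expected_bp


@dataclass
class NormalizedAlignment:
    """An alignment with normalized distances and bookkeeping for later steps."""

    record: AlignmentRecord
    scale: float
    flagged: bool
    ref_sites: np.ndarray   # matched ref site indices, ref-ascending
    q_pos: np.ndarray       # normalized molecule positions, same order
    obs: np.ndarray         # normalized distances between consecutive sites
    exp: np.ndarray
    discarded: bool = False
    corrections: dict[int, float] = field(default_factory=dict)  # pair idx -> delta

    @property
    def molecule_id(self) -> str:
        return self.record.query_id


def normalize_alignment(
    record: AlignmentRecord,
    molecule: LabelMap,
    ref_map: LabelMap,
    params: IndelParams | None = None,
) -> NormalizedAlignment:
    """Normalize one alignment's inter-label distances by its scale factor.

    The scale factor is the median observed/expected ratio over intervals not
    flagged abnormal; alignments with fewer than 2 intervals are passed
    through unnormalized and flagged.
    """
    params = params or IndelParams()
    ref_sites = np.array([r for r, _ in record.site_pairs], dtype=int)
    q_sites = np.array([q for _, q in record.site_pairs], dtype=int)
    q_pos = molecule.positions[q_sites - 1]
    r_pos = ref_map.positions[ref_sites - 1]
    if np.any(ref_sites > ref_map.n_labels):
        raise ValueError(f"{record.query_id}: ref site index out of range")
    obs = np.abs(np.diff(q_pos))
    exp = np.diff(r_pos)
    if obs.size < 2:
        return NormalizedAlignment(record, 1.0, True, ref_sites, q_pos, obs, exp)
    ratios = obs / exp
    scale0 = float(np.median(ratios))
    if scale0 <= 0:
        return NormalizedAlignment(record, 1.0, True, ref_sites, q_pos, obs, exp)
    dev0 = np.abs(obs / scale0 - exp)
    normal = dev0 <= np.maximum(params.abs_threshold_bp, params.rel_threshold * exp)
    if normal.sum() >= 2:
        scale = float(np.median(ratios[normal]))
    else:
        scale = scale0
    return NormalizedAlignment(
        record, scale, False, ref_sites, q_pos / scale, obs / scale, exp
    )


def observations_frame(alignments: list[NormalizedAlignment]) -> pd.DataFrame:
    """Flatten normalized alignments into one row per pair observation."""
    cols = {"aln": [], "mol": [], "ref": [], "ls": [], "rs": [], "obs": [], "exp": []}
    for a_idx, na in enumerate(alignments):
        n = na.obs.size
        if n == 0:
            continue
        cols["aln"].append(np.full(n, a_idx))
        cols["mol"].append(np.full(n, na.molecule_id, dtype=object))
        cols["ref"].append(np.full(n, na.record.ref_id, dtype=object))
        cols["ls"].append(na.ref_sites[:-1])
        cols["rs"].append(na.ref_sites[1:])
        cols["obs"].append(na.obs)
        cols["exp"].append(na.exp)
    if not cols["aln"]:
        return pd.DataFrame(
            columns=["aln", "mol", "ref", "ls", "rs", "obs", "exp", "dev"]
        )
    df = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    df["aln"] = df["aln"].astype(int)
    df["ls"] = df["ls"].astype(int)
    df["rs"] = df["rs"].astype(int)
    df["dev"] = df["obs"] - df["exp"]
    return df
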