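"""Cross-molecule arbitration of abnormal label-pair distances.

At each reference interval, abnormal distances seen consistently (same sign,
similar magnitude) in enough molecules become indel candidates; an isolated
abnormal distance among many normal ones is corrected to the consensus; an
alignment dominated by mutually inconsistent abnormal pairs is discarded.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .observations import NormalizedAlignment
from .params import IndelParams

__all__ = ["arbitrate_abnormal_pairs"]

VERDICTS = ("normal", "candidate", "corrected", "deferred", "unresolved")


def arbitrate_abnormal_pairs(
    df: pd.DataFrame,
    alignments: list[NormalizedAlignment],
    params: IndelParams | None = None,
) -> pd.DataFrame:
    """Assign a verdict to every pair observation (adds columns in place).

    ``df`` is the frame from :func:`observations_frame`.  Adds ``abnormal``,
    ``verdict`` and ``consensus`` columns; marks discarded alignments on the
    ``alignments`` list and records corrections on them.
    """
    params = params or IndelParams()
    if df.empty:
        df["abnormal"] = pd.Series(dtype=bool)
        df["verdict"] = pd.Series(dtype=object)
        df["consensus"] = pd.Series(dtype=float)
        return df
    thr = np.maximum(params.abs_threshold_bp, params.rel_threshold * df["exp"].values)
    df["abnormal"] = np.abs(df["dev"].values) > thr
    df["verdict"] = np.where(df["abnormal"], "unresolved", "normal")
    df["consensus"] = np.nan

    # only intervals containing at least one abnormal observation need work
    abn_keys = df.loc[df["abnormal"], ["ref", "ls", "rs"]].drop_duplicates()
    group_rows = df.groupby(["ref", "ls", "rs"]).indices
    for ref, ls, rs in abn_keys.itertuples(index=False):
        sel = np.asarray(group_rows[(ref, ls, rs)])
        group = df.iloc[sel]
        n = len(group)
        abn = group["abnormal"].values
        if n < params.min_coverage:
            df.iloc[sel[abn], df.columns.get_loc("verdict")] = "deferred"
            continue
        devs = group["dev"].values
        candidate_mask = np.zeros(n, dtype=bool)
        for sign in (1, -1):
            sgn = abn & (np.sign(devs) == sign)
            if sgn.sum() < params.min_support:
                continue
            med = np.median(devs[sgn])
            tol = max(params.magnitude_tol_abs_bp, params.magnitude_tol_frac * abs(med))
            consistent = sgn & (np.abs(devs - med) <= tol)
            if consistent.sum() >= params.min_support:
                candidate_mask |= consistent
        normal_mask = ~abn
        leftover = abn & ~candidate_mask
        df.iloc[sel[candidate_mask], df.columns.get_loc("verdict")] = "candidate"
        if leftover.any() and normal_mask.sum() >= params.min_normal:
            consensus = float(np.median(group["obs"].values[normal_mask]))
            df.iloc[sel[leftover], df.columns.get_loc("verdict")] = "corrected"
            df.iloc[sel[leftover], df.columns.get_loc("consensus")] = consensus

    # discard alignments with too many mutually inconsistent abnormal pairs
    bad = df["abnormal"].values & ~np.isin(df["verdict"].values, ("candidate",))
    per_aln_bad = df.assign(bad=bad).groupby("aln")["bad"].agg(["sum", "count"])
    to_discard = per_aln_bad[
        (per_aln_bad["count"] >= params.min_pairs_for_discard)
        & (per_aln_bad["sum"] / per_aln_bad["count"] > params.max_abnormal_frac)
    ].index
    for a_idx in to_discard:
        alignments[a_idx].discarded = True
    if len(to_discard):
        discarded_rows = df["aln"].isin(to_discard)
        df.loc[discarded_rows, "verdict"] = "discarded"

    # record corrections on their alignments (for spanning-distance fixes)
    corrected = df[df["verdict"] == "corrected"]
    for row in corrected.itertuples():
        na = alignments[row.aln]
        pair_idx = int(np.flatnonzero(na.ref_sites[:-1] == row.ls)[0])
        na.corrections[pair_idx] = float(row.consensus - row.obs)
    return df
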