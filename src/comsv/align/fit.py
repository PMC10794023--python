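"""Dynamic-programming fit alignment of a label map into a reference window.

The score of a monotone matching is

    sum over matched pairs of  match_reward
  - sum over consecutive matched pairs of
        sizing_error_scale * (obs - exp)^2 / (exp * 1000)
  - missed_ref_label_penalty  per reference label skipped between pairs
  - false_molecule_label_penalty  per query label skipped (including leading
    and trailing unmatched query labels; reference flanks are free)

with at most ``band_max_skips`` consecutive skipped labels on either side
between two matched pairs.  Ties are broken toward fewer skipped labels,
then the leftmost reference start, so output is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..formats.maps import AlignmentRecord, LabelMap, SplitAlignmentSet

__all__ = ["ScoringParams", "fit_align", "match_score", "DuplicationEvidence",
           "detect_tandem_dup_by_realign"]


@dataclass
class ScoringParams:
    match_reward: float = 3.0
    missed_ref_label_penalty: float = 1.0
    false_molecule_label_penalty: float = 1.0
    sizing_error_scale: float = 2.0
    min_segment_score: float = 9.0
    band_max_skips: int = 3

    def __post_init__(self) -> None:
        if self.missed_ref_label_penalty < 0 or self.false_molecule_label_penalty < 0:
            raise ValueError("penalties must be >= 0")
        if self.band_max_skips < 0:
            raise ValueError("band_max_skips must be >= 0")


def match_score(
    query: np.ndarray, ref: np.ndarray, pairs: list[tuple[int, int]], params: ScoringParams
) -> float:
    """Score an explicit monotone matching (0-based index pairs, query-side

    ascending).  Shared by the DP and by brute-force oracles in the tests.
    Returns ``-inf`` for matchings that violate the skip band.
    """
    if not pairs:
        return -np.inf
    score = params.match_reward * len(pairs)
    score -= params.false_molecule_label_penalty * pairs[0][0]
    score -= params.false_molecule_label_penalty * (len(query) - 1 - pairs[-1][0])
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        qskip, rskip = i1 - i0 - 1, j1 - j0 - 1
        if qskip < 0 or rskip < 0:
            return -np.inf
        if qskip > params.band_max_skips or rskip > params.band_max_skips:
            return -np.inf
        score -= params.false_molecule_label_penalty * qskip
        score -= params.missed_ref_label_penalty * rskip
        obs = query[i1] - query[i0]
        exp = ref[j1] - ref[j0]
        score -= params.sizing_error_scale * (obs - exp) ** 2 / (exp * 1000.0)
    return float(score)


def _dp_best(query: np.ndarray, ref: np.ndarray, params: ScoringParams):
    """Best matching with >= 2 pairs; returns (score, nskips, pairs) or None."""
    m, n = len(query), len(ref)
    band = params.band_max_skips
    mr, flp, mrp = params.match_reward, params.false_molecule_label_penalty, params.missed_ref_label_penalty
    NEG = -np.inf
    score = np.full((m, n), NEG)
    skips = np.zeros((m, n), dtype=int)
    length = np.ones((m, n), dtype=int)
    parent = np.full((m, n, 2), -1, dtype=int)
    for i in range(m):
        for j in range(n):
            # start a new chain at (i, j): leading query labels are skipped
            best_s = mr - flp * i
            best_k = i
            best_len = 1
            best_par = (-1, -1)
            for pi in range(max(0, i - 1 - band), i):
                qskip = i - pi - 1
                for pj in range(max(0, j - 1 - band), j):
                    if score[pi, pj] == NEG:
                        continue
                    rskip = j - pj - 1
                    exp = ref[j] - ref[pj]
                    obs = query[i] - query[pi]
                    s = (
                        score[pi, pj] + mr - flp * qskip - mrp * rskip
                        - params.sizing_error_scale * (obs - exp) ** 2 / (exp * 1000.0)
                    )
                    k = skips[pi, pj] + qskip + rskip
                    if s > best_s + 1e-9 or (
                        abs(s - best_s) <= 1e-9
                        and (k < best_k or (k == best_k and pj < best_par[1]))
                    ):
                        best_s, best_k = s, k
                        best_len = length[pi, pj] + 1
                        best_par = (pi, pj)
            score[i, j] = best_s
            skips[i, j] = best_k
            length[i, j] = best_len
            parent[i, j] = best_par
    best = None
    for i in range(m):
        for j in range(n):
            if length[i, j] < 2:
                continue
            trailing = m - 1 - i
            s = score[i, j] - flp * trailing
            k = skips[i, j] + trailing
            cand = (s, k, i, j)
            if best is None or s > best[0] + 1e-9 or (
                abs(s - best[0]) <= 1e-9
                and (k < best[1] or (k == best[1] and j < best[3]))
            ):
                best = cand
    if best is None:
        return None
    s, k, i, j = best
    pairs = []
    while i >= 0:
        pairs.append((i, j))
        i, j = parent[i, j]
    pairs.reverse()
    return s, k, pairs


def fit_align(
    query_labels: np.ndarray,
    ref_window_labels: np.ndarray,
    params: ScoringParams | None = None,
    try_both_orientations: bool = True,
    query_id: str = "query",
    ref_id: str = "ref",
) -> AlignmentRecord | None:
    """Fit-align a whole query label array into a reference window.

    Returns the best-scoring :class:`AlignmentRecord` (site indices are
    1-based positions within the given arrays) or None if the best score is
    below ``min_segment_score`` or fewer than 2 query labels are available.
    """
    params = params or ScoringParams()
    query = np.asarray(query_labels, dtype=float)
    ref = np.asarray(ref_window_labels, dtype=float)
    if query.size < 2 or ref.size < 2:
        return None
    candidates = []
    fwd = _dp_best(query, ref, params)
    if fwd is not None:
        candidates.append(("+", fwd))
    if try_both_orientations:
        flipped = (query.max() - query)[::-1]  # mirror distances
        rev = _dp_best(flipped, ref, params)
        if rev is not None:
            candidates.append(("-", rev))
    best = None
    for orientation, (s, k, pairs) in candidates:
        if best is None or s > best[1] + 1e-9 or (abs(s - best[1]) <= 1e-9 and orientation == "+"):
            best = (orientation, s, k, pairs)
    if best is None or best[1] < params.min_segment_score:
        return None
    orientation, s, _, pairs = best
    m = query.size
    site_pairs = []
    for qi, rj in pairs:
        q_site = qi + 1 if orientation == "+" else m - qi
        site_pairs.append((rj + 1, q_site))
    q_positions = [query[q - 1] for _, q in site_pairs]
    r_positions = [ref[r - 1] for r, _ in site_pairs]
    return AlignmentRecord(
        query_id=query_id,
        ref_id=ref_id,
        orientation=orientation,
        query_start_bp=q_positions[0],
        query_end_bp=q_positions[-1],
        ref_start_bp=r_positions[0],
        ref_end_bp=r_positions[-1],
        site_pairs=site_pairs,
        confidence=s,
    )


@dataclass
class DuplicationEvidence:
    molecule_id: str
    ref_id: str
    unit_start_bp: float
    unit_end_bp: float
    score: float


def detect_tandem_dup_by_realign(
    split_set: SplitAlignmentSet,
    molecule: LabelMap,
    ref_map: LabelMap,
    params: ScoringParams | None = None,
    min_unaligned_labels: int = 4,
    flank_bp: float = 50_000.0,
) -> DuplicationEvidence | None:
    """Re-align unaligned molecule stretches onto their neighbor's reference

    span; an alignment overlapping the already-aligned interval is evidence
    for a tandem duplication (the unaligned part is the extra copy).
    """
    params = params or ScoringParams()
    matched_q = {
        q for seg in split_set.segments for _, q in seg.site_pairs
    }
    for lo, hi in split_set.unaligned_intervals:
        un_idx = [
            i + 1
            for i, p in enumerate(molecule.positions)
            if lo <= p <= hi and (i + 1) not in matched_q
        ]
        if len(un_idx) < min_unaligned_labels:
            continue
        # pick the aligned segment adjacent to this interval on the query
        adjacent = None
        for seg in split_set.segments:
            q0, q1 = sorted((seg.query_start_bp, seg.query_end_bp))
            if abs(q0 - hi) < 1e3 or abs(q1 - lo) < 1e3 or (q1 >= lo and q0 <= hi):
                if seg.ref_id == ref_map.map_id:
                    adjacent = seg
                    break
        if adjacent is None:
            continue
        win_lo = adjacent.ref_start_bp - flank_bp
        win_hi = adjacent.ref_end_bp + flank_bp
        w0 = int(np.searchsorted(ref_map.positions, win_lo))
        w1 = int(np.searchsorted(ref_map.positions, win_hi))
        window = ref_map.positions[w0:w1]
        qpos = molecule.positions[[i - 1 for i in un_idx]]
        hit = fit_align(qpos, window, params, query_id=split_set.query_id,
                        ref_id=ref_map.map_id)
        if hit is None:
            continue
        # demand a clean, near-complete fit: random label runs reach the raw
        # score floor surprisingly often but pay heavy sizing penalties
        if hit.n_pairs < min(4, min_unaligned_labels):
            continue
        if hit.confidence < 0.6 * params.match_reward * hit.n_pairs:
            continue
        hit_lo = ref_map.positions[w0 + min(r for r, _ in hit.site_pairs) - 1]
        hit_hi = ref_map.positions[w0 + max(r for r, _ in hit.site_pairs) - 1]
        ov_lo = max(hit_lo, adjacent.ref_start_bp)
        ov_hi = min(hit_hi, adjacent.ref_end_bp)
        if ov_hi > ov_lo:
            return DuplicationEvidence(
                molecule_id=split_set.query_id,
                ref_id=ref_map.map_id,
                unit_start_bp=ov_lo,
                unit_end_bp=ov_hi,
                score=hit.confidence,
            )
    return None
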