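"""Core in-memory types: label maps, alignments and split-alignment sets.

Coordinates are 1-based inclusive base pairs throughout, matching the CMAP/XMAP
conventions.  Positions are kept as floats internally and only rounded to one
decimal place at write time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LabelMap",
    "AlignmentRecord",
    "SplitAlignmentSet",
    "group_split_sets",
]


@dataclass
class LabelMap:
    """An ordered set of label positions on one DNA entity.

    Parameters
    ----------
    map_id : str
        Identifier of the molecule / contig / reference map.
    length_bp : float
        Total length of the entity; must be positive.
    positions : array-like of float
        Strictly increasing label positions in ``(0, length_bp]``.
    channels : array-like of int, optional
        Label channel per position (defaults to channel 1).
    flagged_short : bool
        Set by readers for molecules shorter than a configured minimum; such
        molecules are retained but callers may choose to skip them.
    """

    map_id: str
    length_bp: float
    positions: np.ndarray
    channels: np.ndarray | None = None
    flagged_short: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.length_bp <= 0:
            raise ValueError(f"map {self.map_id}: length_bp must be > 0")
        if self.positions.ndim != 1:
            raise ValueError("positions must be a 1-D array")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError(f"map {self.map_id}: positions not strictly increasing")
            if self.positions[0] <= 0 or self.positions[-1] > self.length_bp + 1e-6:
                raise ValueError(
                    f"map {self.map_id}: positions must lie in (0, length_bp]"
                )
        if self.channels is None:
            self.channels = np.ones(self.positions.size, dtype=int)
        else:
            self.channels = np.asarray(self.channels, dtype=int)
            if self.channels.shape != self.positions.shape:
                raise ValueError("channels must parallel positions")

    @property
    def n_labels(self) -> int:
        return int(self.positions.size)

    def __eq__(self, other: object) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, LabelMap):
            return NotImplemented
        return (
            self.map_id == other.map_id
            and abs(self.length_bp - other.length_bp) < 0.1
            and self.positions.size == other.positions.size
            and bool(np.all(np.abs(self.positions - other.positions) < 0.1))
        )


@dataclass
class AlignmentRecord:
    """One aligned segment of a query map against a reference map.

    ``site_pairs`` is an ordered list of ``(ref_site, query_site)`` 1-based
    site indices, strictly increasing in the reference index, and strictly
    increasing (orientation ``+``) or decreasing (``-``) in the query index.
    """

    query_id: str
    ref_id: str
    orientation: str
    query_start_bp: float
    query_end_bp: float
    ref_start_bp: float
    ref_end_bp: float
    site_pairs: list[tuple[int, int]]
    confidence: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if len(self.site_pairs) < 2:
            raise ValueError("an alignment needs at least 2 site pairs")
        self.site_pairs = [(int(r), int(q)) for r, q in self.site_pairs]
        ref_idx = [r for r, _ in self.site_pairs]
        qry_idx = [q for _, q in self.site_pairs]
        if any(b <= a for a, b in zip(ref_idx, ref_idx[1:])):
            raise ValueError(f"{self.query_id}: ref site indices not strictly increasing")
        diffs = [b - a for a, b in zip(qry_idx, qry_idx[1:])]
        if self.orientation == "+" and any(d <= 0 for d in diffs):
            raise ValueError(f"{self.query_id}: '+' alignment with non-increasing query sites")
        if self.orientation == "-" and any(d >= 0 for d in diffs):
            raise ValueError(f"{self.query_id}: '-' alignment with non-decreasing query sites")

    @property
    def n_pairs(self) -> int:
        return len(self.site_pairs)

    def query_ordered_pairs(self) -> list[tuple[int, int]]:
        """Site pairs re-ordered so query indices ascend (helper for '-')."""
        if self.orientation == "+":
            return list(self.site_pairs)
        return list(reversed(self.site_pairs))


@dataclass
class SplitAlignmentSet:
    """All aligned segments of one query, ordered along the query."""

    query_id: str
    segments: list[AlignmentRecord]
    unaligned_intervals: list[tuple[float, float]]
    query_length_bp: float | None = None

    @classmethod
    def from_records(
        cls,
        records: Sequence[AlignmentRecord],
        query_length_bp: float | None = None,
        overlap_slack_bp: float = 500.0,
    ) -> "SplitAlignmentSet":
        if not records:
            raise ValueError("cannot build a split set from zero records")
        qid = records[0].query_id
        if any(r.query_id != qid for r in records):
            raise ValueError("records in a split set must share query_id")
        segs = sorted(records, key=lambda r: min(r.query_start_bp, r.query_end_bp))
        # query intervals, normalized low..high
        ivs = [tuple(sorted((r.query_start_bp, r.query_end_bp))) for r in segs]
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1 - overlap_slack_bp:
                raise ValueError(
                    f"{qid}: segments overlap on the query by more than slack "
                    f"({a1 - b0:.0f} bp)"
                )
        unaligned: list[tuple[float, float]] = []
        cursor = 0.0
        for lo, hi in ivs:
            if lo > cursor:
                unaligned.append((cursor, lo))
            cursor = max(cursor, hi)
        end = query_length_bp if query_length_bp is not None else cursor
        if end > cursor:
            unaligned.append((cursor, end))
        return cls(qid, segs, unaligned, query_length_bp=query_length_bp)


def group_split_sets(
    records: Iterable[AlignmentRecord],
    query_lengths: dict[str, float] | None = None,
    overlap_slack_bp: float = 500.0,
) -> list[SplitAlignmentSet]:
    """Group alignment records by query id into :class:`SplitAlignmentSet`s."""
    by_query: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_query.setdefault(rec.query_id, []).append(rec)
    out = []
    for qid in sorted(by_query):
        length = query_lengths.get(qid) if query_lengths else None
        out.append(
            SplitAlignmentSet.from_records(
                by_query[qid], query_length_bp=length, overlap_slack_bp=overlap_slack_bp
            )
        )
    return out
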