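"""XMAP alignment reader and writer.

The ``Alignment`` column is the usual ``(refSite,qrySite)(...)...`` string;
it is parsed into ordered site pairs.  Extra columns beyond the standard set
are preserved as opaque strings and written back.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

from .maps import AlignmentRecord

__all__ = ["read_xmap", "write_xmap", "parse_alignment_string", "XmapParseError"]

_COLUMNS = [
    "XmapEntryID",
    "QryContigID",
    "RefContigID",
    "QryStartPos",
    "QryEndPos",
    "RefStartPos",
    "RefEndPos",
    "Orientation",
    "Confidence",
    "HitEnum",
    "QryLen",
    "RefLen",
    "LabelChannel",
    "Alignment",
]

_PAIR_RE = re.compile(r"\((\d+),(\d+)\)")


class XmapParseError(ValueError):
    pass


def parse_alignment_string(s: str) -> list[tuple[int, int]]:
    """Parse ``(1,1)(2,2)...`` into ``[(1, 1), (2, 2), ...]``."""
    pairs = [(int(r), int(q)) for r, q in _PAIR_RE.findall(s)]
    rebuilt = "".join(f"({r},{q})" for r, q in pairs)
    if rebuilt != s.strip():
        raise XmapParseError(f"malformed alignment string: {s!r}")
    return pairs


def read_xmap(path: str | Path) -> list[AlignmentRecord]:
    path = Path(path)
    header_cols: list[str] | None = None
    records: list[AlignmentRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#h"):
                    header_cols = line[2:].split()
                continue
            fields = line.split("\t")
            cols = header_cols or _COLUMNS
            if len(fields) < len(cols):
                raise XmapParseError(f"line {lineno}: expected {len(cols)} columns")
            row = dict(zip(cols, fields))
            try:
                pairs = parse_alignment_string(row["Alignment"])
            except XmapParseError as exc:
                raise XmapParseError(f"line {lineno}: {exc}") from None
            extra = {k: v for k, v in zip(cols, fields) if k not in _COLUMNS}
            records.append(
                AlignmentRecord(
                    query_id=row["QryContigID"],
                    ref_id=row["RefContigID"],
                    orientation=row["Orientation"],
                    query_start_bp=float(row["QryStartPos"]),
                    query_end_bp=float(row["QryEndPos"]),
                    ref_start_bp=float(row["RefStartPos"]),
                    ref_end_bp=float(row["RefEndPos"]),
                    site_pairs=pairs,
                    confidence=float(row["Confidence"]),
                    extra=extra,
                )
            )
    return records


def write_xmap(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    path = Path(path)
    extra_cols: list[str] = []
    for rec in records:
        for k in rec.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    with path.open("w") as fh:
        fh.write("# XMAP File Version:\t0.2\n")
        fh.write("#h " + " ".join(_COLUMNS + extra_cols) + "\n")
        for i, rec in enumerate(records, start=1):
            aln = "".join(f"({r},{q})" for r, q in rec.site_pairs)
            n = rec.n_pairs
            fields = [
                str(i),
                rec.query_id,
                rec.ref_id,
                f"{rec.query_start_bp:.1f}",
                f"{rec.query_end_bp:.1f}",
                f"{rec.ref_start_bp:.1f}",
                f"{rec.ref_end_bp:.1f}",
                rec.orientation,
                f"{rec.confidence:.2f}",
                f"{n}M",
                f"{rec.extra.get('QryLen', max(rec.query_start_bp, rec.query_end_bp))}",
                f"{rec.extra.get('RefLen', rec.ref_end_bp)}",
                "1",
                aln,
            ]
            fields += [str(rec.extra.get(k, "")) for k in extra_cols]
            fh.write("\t".join(fields) + "\n")
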