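"""Plain-text truth table I/O for simulated datasets."""
from __future__ import annotations

from pathlib import Path

from .events import SVEvent, TruthRecord

__all__ = ["write_truth_tsv", "read_truth_tsv"]

_COLUMNS = [
    "sv_id", "type", "ref_id", "start", "end", "size", "zygosity",
    "origin_clone", "dest_ref_id", "dest_bp", "expected_support_fraction",
]


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for t in truth:
            sv = t.sv
            fh.write(
                "\t".join(
                    [
                        sv.sv_id, sv.sv_type, sv.ref_id, f"{sv.start_bp:.1f}",
                        f"{sv.end_bp:.1f}", f"{sv.size_bp:.1f}", sv.zygosity,
                        t.origin_clone, sv.dest_ref_id or ".",
                        f"{sv.dest_bp:.1f}" if sv.dest_bp is not None else ".",
                        f"{t.expected_support_fraction:.6f}",
                    ]
                )
                + "\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    path = Path(path)
    out = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            sv = SVEvent(
                sv_id=row["sv_id"],
                sv_type=row["type"],
                ref_id=row["ref_id"],
                start_bp=float(row["start"]),
                end_bp=float(row["end"]),
                size_bp=float(row["size"]) if float(row["size"]) > 0 else (
                    1.0 if row["type"] in ("insertion", "deletion", "duplication") else 0.0
                ),
                zygosity=row["zygosity"],
                origin_clone=row["origin_clone"],
                dest_ref_id=None if row["dest_ref_id"] == "." else row["dest_ref_id"],
                dest_bp=None if row["dest_bp"] == "." else float(row["dest_bp"]),
                novel_label_offsets=[] if row["type"] == "insertion" else None,
            )
            out.append(
                TruthRecord(
                    sv=sv,
                    expected_support_fraction=float(row["expected_support_fraction"]),
                    ref_id=sv.ref_id,
                    start_bp=sv.start_bp,
                    end_bp=sv.end_bp,
                    origin_clone=sv.origin_clone,
                )
            )
    return out
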