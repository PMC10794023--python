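"""Unified SV call record shared by both pipelines, plus TSV/VCF export."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["SVCall", "write_calls_tsv", "read_calls_tsv", "write_calls_vcf"]

SV_TYPES = (
    "insertion",
    "deletion",
    "inversion",
    "duplication",
    "translocation_intra",
    "translocation_inter",
)

_SYMBOLIC_ALT = {
    "insertion": "<INS>",
    "deletion": "<DEL>",
    "inversion": "<INV>",
    "duplication": "<DUP>",
}


@dataclass
class SVCall:
    """A typed structural-variant call from either pipeline."""

    call_id: str
    sv_type: str
    ref_id: str
    start_bp: float
    end_bp: float
    size_bp: float
    zygosity: str = "unknown"
    allele_fraction: float = float("nan")
    support: int = 0
    total: int = 0
    status: str = "complete"
    confidence: float = 0.0
    source: str = ""
    # second locus for translocations / breakend-style events
    ref_id_b: str | None = None
    pos_b: float | None = None
    # anchor-to-anchor enclosing interval for indel calls
    region_start_bp: float | None = None
    region_end_bp: float | None = None
    genes: list[str] = field(default_factory=list)
    cross_ref: str | None = None
    supporting_molecules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.status not in ("complete", "partial"):
            raise ValueError(f"status must be complete|partial, got {self.status!r}")


_TSV_COLUMNS = [
    "call_id", "type", "ref_id", "start", "end", "size", "zygosity",
    "allele_fraction", "support", "total", "status", "confidence", "source",
    "ref_id_b", "pos_b", "region_start", "region_end", "genes", "cross_ref",
]


def write_calls_tsv(calls: Sequence[SVCall], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for c in calls:
            row = [
                c.call_id, c.sv_type, c.ref_id, f"{c.start_bp:.1f}", f"{c.end_bp:.1f}",
                f"{c.size_bp:.1f}", c.zygosity, f"{c.allele_fraction:.4f}",
                str(c.support), str(c.total), c.status, f"{c.confidence:.4f}", c.source,
                c.ref_id_b or ".", f"{c.pos_b:.1f}" if c.pos_b is not None else ".",
                f"{c.region_start_bp:.1f}" if c.region_start_bp is not None else ".",
                f"{c.region_end_bp:.1f}" if c.region_end_bp is not None else ".",
                ",".join(c.genes) if c.genes else ".",
                c.cross_ref or ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_calls_tsv(path: str | Path) -> list[SVCall]:
    path = Path(path)
    calls = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            calls.append(
                SVCall(
                    call_id=row["call_id"],
                    sv_type=row["type"],
                    ref_id=row["ref_id"],
                    start_bp=float(row["start"]),
                    end_bp=float(row["end"]),
                    size_bp=float(row["size"]),
                    zygosity=row["zygosity"],
                    allele_fraction=float(row["allele_fraction"]),
                    support=int(row["support"]),
                    total=int(row["total"]),
                    status=row["status"],
                    confidence=float(row["confidence"]),
                    source=row.get("source", ""),
                    ref_id_b=None if row.get("ref_id_b", ".") == "." else row["ref_id_b"],
                    pos_b=None if row.get("pos_b", ".") == "." else float(row["pos_b"]),
                    region_start_bp=None if row.get("region_start", ".") == "." else float(row["region_start"]),
                    region_end_bp=None if row.get("region_end", ".") == "." else float(row["region_end"]),
                    genes=[] if row.get("genes", ".") == "." else row["genes"].split(","),
                    cross_ref=None if row.get("cross_ref", ".") == "." else row["cross_ref"],
                )
            )
    return calls


def write_calls_vcf(
    calls: Sequence[SVCall], path: str | Path, contig_lengths: dict[str, float] | None = None
) -> None:
    """Minimal VCF 4.2 with symbolic ALTs; translocations as BND pairs."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting molecules">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,Description="complete or partial">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        if contig_lengths:
            for cid, clen in contig_lengths.items():
                fh.write(f"##contig=<ID={cid},length={int(clen)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            qual = f"{max(0.0, min(1.0, c.confidence)) * 100:.0f}"
            common = f"SUPPORT={c.support};AF={0.0 if c.allele_fraction != c.allele_fraction else c.allele_fraction:.4f};STATUS={c.status}"
            if c.sv_type in _SYMBOLIC_ALT:
                svlen = int(c.size_bp) if c.sv_type != "deletion" else -int(c.size_bp)
                info = (
                    f"SVTYPE={_SYMBOLIC_ALT[c.sv_type][1:-1]};END={int(c.end_bp)};"
                    f"SVLEN={svlen};{common}"
                )
                fh.write(
                    f"{c.ref_id}\t{int(c.start_bp)}\t{c.call_id}\tN\t"
                    f"{_SYMBOLIC_ALT[c.sv_type]}\t{qual}\tPASS\t{info}\n"
                )
            else:  # translocation -> breakend pair
                ref_b = c.ref_id_b or c.ref_id
                pos_b = int(c.pos_b) if c.pos_b is not None else int(c.end_bp)
                a_id, b_id = f"{c.call_id}_bnd_a", f"{c.call_id}_bnd_b"
                fh.write(
                    f"{c.ref_id}\t{int(c.start_bp)}\t{a_id}\tN\tN[{ref_b}:{pos_b}[\t"
                    f"{qual}\tPASS\tSVTYPE=BND;MATEID={b_id};{common}\n"
                )
                fh.write(
                    f"{ref_b}\t{pos_b}\t{b_id}\tN\t]{c.ref_id}:{int(c.start_bp)}]N\t"
                    f"{qual}\tPASS\tSVTYPE=BND;MATEID={a_id};{common}\n"
                )
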