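"""CMAP consensus/reference map reader and writer."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .maps import LabelMap

__all__ = ["read_cmap", "write_cmap"]

_COLUMNS = [
    "CMapId",
    "ContigLength",
    "NumSites",
    "SiteID",
    "LabelChannel",
    "Position",
    "StdDev",
    "Coverage",
    "Occurrence",
]


def read_cmap(path: str | Path) -> list[LabelMap]:
    """Read a CMAP file; channel-0 end-marker rows are skipped."""
    path = Path(path)
    header_cols: list[str] | None = None
    by_map: dict[str, dict] = {}
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#h"):
                    header_cols = line[2:].split()
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            cols = header_cols or _COLUMNS
            row = dict(zip(cols, fields))
            map_id = row["CMapId"]
            entry = by_map.setdefault(
                map_id, {"length": float(row["ContigLength"]), "sites": []}
            )
            if int(row["LabelChannel"]) == 0:
                continue  # terminal end-marker row
            entry["sites"].append(
                (int(row["SiteID"]), int(row["LabelChannel"]), float(row["Position"]))
            )
    maps = []
    for map_id in sorted(by_map, key=lambda m: (len(m), m)):
        entry = by_map[map_id]
        sites = sorted(entry["sites"])
        pos = np.array([p for _, _, p in sites])
        chan = np.array([c for _, c, _ in sites], dtype=int)
        maps.append(LabelMap(map_id, entry["length"], pos, chan))
    return maps


def write_cmap(maps: Sequence[LabelMap], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# CMAP File Version:\t0.1\n")
        fh.write("# Label Channels:\t1\n")
        fh.write("#h " + " ".join(_COLUMNS) + "\n")
        fh.write("#f int float int int int float float float float\n")
        for m in maps:
            n = m.n_labels
            for i, (p, c) in enumerate(zip(m.positions, m.channels), start=1):
                fh.write(
                    f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{i}\t{int(c)}\t{p:.1f}"
                    f"\t1.0\t1.0\t1.0\n"
                )
            fh.write(
                f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{n + 1}\t0\t{m.length_bp:.1f}"
                f"\t0.0\t1.0\t0.0\n"
            )
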