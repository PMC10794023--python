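"""Reader/writer for the BNX molecule format (v1.2 / v1.3 dialects).

Only the information the pipelines use is modeled: per-molecule id, length
and per-channel label positions.  ``QX``-style per-label quality lines are
ignored on read and never written.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .maps import LabelMap

__all__ = ["read_bnx", "write_bnx", "BnxParseError"]


class BnxParseError(ValueError):
    pass


def read_bnx(path: str | Path, min_length_bp: float = 0.0) -> list[LabelMap]:
    """Parse a BNX file into one :class:`LabelMap` per molecule.

    The trailing molecule-end sentinel on a label line (a final value equal to
    the molecule length) is dropped.  Molecules with non-monotone positions are
    rejected with a warning; molecules shorter than ``min_length_bp`` are kept
    but flagged.
    """
    molecules: list[LabelMap] = []
    cur_id: str | None = None
    cur_len: float | None = None
    cur_pos: list[np.ndarray] = []
    cur_chan: list[np.ndarray] = []
    cur_bad = False

    def _flush(lineno: int) -> None:
        nonlocal cur_id, cur_len, cur_pos, cur_chan, cur_bad
        if cur_id is None:
            return
        if cur_pos:
            pos = np.concatenate(cur_pos)
            chan = np.concatenate(cur_chan)
            order = np.argsort(pos, kind="stable")
            pos, chan = pos[order], chan[order]
        else:
            pos = np.empty(0)
            chan = np.empty(0, dtype=int)
        if cur_bad or (pos.size and np.any(np.diff(pos) <= 0)):
            warnings.warn(
                f"BNX molecule {cur_id} (before line {lineno}): "
                "non-monotone label positions, molecule skipped"
            )
        else:
            molecules.append(
                LabelMap(
                    cur_id,
                    float(cur_len),
                    pos,
                    chan,
                    flagged_short=float(cur_len) < min_length_bp,
                )
            )
        cur_id, cur_len, cur_pos, cur_chan, cur_bad = None, None, [], [], False

    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            tag = fields[0]
            if tag == "0":
                _flush(lineno)
                if len(fields) < 3:
                    raise BnxParseError(f"line {lineno}: malformed molecule header")
                cur_id = fields[1]
                cur_len = float(fields[2])
            elif tag.isdigit():
                if cur_id is None:
                    raise BnxParseError(
                        f"line {lineno}: label line before any molecule header"
                    )
                channel = int(tag)
                vals = np.array([float(v) for v in fields[1:]], dtype=float)
                # drop molecule-end sentinel (final value equal to the length)
                if vals.size and abs(vals[-1] - cur_len) < 0.11:
                    vals = vals[:-1]
                if vals.size and np.any(np.diff(vals) <= 0):
                    cur_bad = True  # per-channel positions must ascend as written
                vals = vals[vals > 0]
                cur_pos.append(vals)
                cur_chan.append(np.full(vals.size, channel, dtype=int))
            elif tag.startswith("Q"):
                continue  # per-label quality, unused
            else:
                raise BnxParseError(f"line {lineno}: unrecognized line tag {tag!r}")
        _flush(lineno if "lineno" in locals() else 0)
    return molecules


def write_bnx(molecules: Sequence[LabelMap], path: str | Path, version: str = "1.2") -> None:
    """Write molecules as BNX; output is re-readable by :func:`read_bnx`."""
    path = Path(path)
    channels = sorted({int(c) for m in molecules for c in np.unique(m.channels)} or {1})
    with path.open("w") as fh:
        fh.write(f"# BNX File Version:\t{version}\n")
        fh.write(f"# Label Channels:\t{len(channels)}\n")
        fh.write("#0h\tLabelChannel\tMoleculeId\tLength\n")
        fh.write("#0f\tint\tint\tfloat\n")
        for mol in molecules:
            fh.write(f"0\t{mol.map_id}\t{mol.length_bp:.1f}\n")
            for ch in channels:
                vals = mol.positions[mol.channels == ch]
                parts = [f"{ch}"] + [f"{v:.1f}" for v in vals] + [f"{mol.length_bp:.1f}"]
                fh.write("\t".join(parts) + "\n")
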