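"""In-silico digestion: turn a DNA sequence into a label map.

Label placement convention
--------------------------
For a motif occurrence whose 5' start is at 1-based position ``s`` on the
forward strand, the label is placed at ``s + label_offset + 1``.  For an
occurrence on the reverse strand the coordinate is mirrored: with the motif's
5' start at forward 1-based position ``s'`` (the rightmost base of the
matched window), the label lands at ``s' - label_offset - 1``.  Palindromic
motifs (equal to their own reverse complement) describe a single labeling
site and are scanned on the forward strand only.  Duplicate positions from
overlapping occurrences are collapsed; positions falling outside
``[1, len(sequence)]`` are dropped.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .maps import LabelMap

__all__ = ["MotifSpec", "in_silico_digest", "reverse_complement"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """An enzyme recognition motif and where its label lands.

    ``label_offset`` is the distance in bp from the motif's 5' start to the
    labeled position (0 means the first motif base is labeled).
    """

    recognition_sequence: str
    label_offset: int = 0
    channel: int = 1

    def __post_init__(self) -> None:
        seq = self.recognition_sequence.upper()
        if not seq:
            raise ValueError("recognition_sequence must be non-empty")
        bad = set(seq) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in motif: {sorted(bad)}")
        if self.label_offset < 0:
            raise ValueError("label_offset must be >= 0")
        object.__setattr__(self, "recognition_sequence", seq)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition_sequence) == self.recognition_sequence


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in motif) + ")")


def in_silico_digest(
    sequence: str, motifs: list[MotifSpec] | MotifSpec, map_id: str = "digest"
) -> LabelMap:
    """Digest ``sequence`` with one or more motifs into a :class:`LabelMap`."""
    if isinstance(motifs, MotifSpec):
        motifs = [motifs]
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot digest an empty sequence (length must be > 0)")
    positions: list[float] = []
    channels: list[int] = []
    for motif in motifs:
        m = motif.recognition_sequence
        length = len(m)
        fwd = [hit.start() for hit in _motif_regex(m).finditer(seq)]
        positions.extend(i + motif.label_offset + 2 for i in fwd)
        channels.extend(motif.channel for _ in fwd)
        if not motif.is_palindromic:
            rev = [hit.start() for hit in _motif_regex(reverse_complement(m)).finditer(seq)]
            positions.extend(i + length - motif.label_offset - 1 for i in rev)
            channels.extend(motif.channel for _ in rev)
    if positions:
        pos = np.array(positions, dtype=float)
        chan = np.array(channels, dtype=int)
        ok = (pos >= 1) & (pos <= len(seq))
        pos, chan = pos[ok], chan[ok]
        order = np.argsort(pos, kind="stable")
        pos, chan = pos[order], chan[order]
        keep = np.concatenate([[True], np.diff(pos) > 0])
        pos, chan = pos[keep], chan[keep]
    else:
        pos = np.empty(0)
        chan = np.empty(0, dtype=int)
    return LabelMap(map_id, float(len(seq)), pos, chan)
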