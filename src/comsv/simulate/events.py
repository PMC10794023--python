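"""SV events, clone evolution graphs, mixtures, noise models and truth records."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SVEvent",
    "CloneGraph",
    "MixtureSpec",
    "NoiseModel",
    "TruthRecord",
    "SPAN_TYPES",
]

SPAN_TYPES = ("deletion", "inversion", "duplication", "translocation_intra")


@dataclass
class SVEvent:
    """One simulated structural variant.

    For insertions, ``end_bp == start_bp`` (the insertion point) and
    ``novel_label_offsets`` holds the label pattern of the inserted material
    (offsets within the insert, at the clone's ambient density).  Inter
    translocations are reciprocal tail swaps: the tails of ``ref_id`` (from
    ``start_bp``) and ``dest_ref_id`` (from ``dest_bp``) are exchanged.
    Intra translocations cut ``[start_bp, end_bp)`` and re-insert it at
    ``dest_bp`` on the same chromosome.
    """

    sv_id: str
    sv_type: str
    ref_id: str
    start_bp: float
    end_bp: float
    size_bp: float = 0.0
    zygosity: str = "het"
    origin_clone: str = ""
    dest_ref_id: str | None = None
    dest_bp: float | None = None
    hap: int = 0  # haplotype carrying a het event
    novel_label_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in (
            "insertion", "deletion", "inversion", "duplication",
            "translocation_intra", "translocation_inter",
        ):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be het or hom")
        if self.sv_type in ("insertion", "deletion", "duplication") and self.size_bp <= 0:
            raise ValueError(f"{self.sv_id}: size_bp must be > 0")
        if self.sv_type in ("deletion", "inversion", "duplication", "translocation_intra"):
            if not self.start_bp < self.end_bp:
                raise ValueError(f"{self.sv_id}: span types need start < end")
        if self.sv_type == "insertion" and self.end_bp != self.start_bp:
            raise ValueError(f"{self.sv_id}: insertion must have end == start")
        if self.sv_type.startswith("translocation") and self.dest_bp is None:
            raise ValueError(f"{self.sv_id}: translocation needs a destination")
        if self.sv_type == "translocation_inter" and self.dest_ref_id is None:
            raise ValueError(f"{self.sv_id}: inter translocation needs dest_ref_id")
        if self.sv_type == "inversion":
            self.size_bp = self.end_bp - self.start_bp

    def haplotypes(self) -> tuple[int, ...]:
        return (0, 1) if self.zygosity == "hom" else (self.hap,)

    def dosage(self) -> int:
        return 2 if self.zygosity == "hom" else 1


@dataclass
class CloneGraph:
    """A rooted cancer-evolution graph: each clone inherits its parent's SVs.

    ``private`` maps clone name to the SVs introduced at that clone;
    ``parent`` maps clone name to its parent (root clones map to None).
    """

    private: dict[str, list[SVEvent]]
    parent: dict[str, str | None]

    def __post_init__(self) -> None:
        for clone, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"clone {clone} has unknown parent {par}")

    @property
    def clones(self) -> list[str]:
        return list(self.private)

    def sv_set(self, clone: str) -> list[SVEvent]:
        """All SVs carried by ``clone`` (inherited plus private), root first."""
        chain = []
        cur: str | None = clone
        while cur is not None:
            chain.append(cur)
            cur = self.parent[cur]
        svs: list[SVEvent] = []
        for c in reversed(chain):
            svs.extend(self.private[c])
        return svs

    def all_events(self) -> list[SVEvent]:
        out = []
        for clone in self.private:
            out.extend(self.private[clone])
        return out

    def carriers(self, sv: SVEvent) -> list[str]:
        return [c for c in self.private if any(e.sv_id == sv.sv_id for e in self.sv_set(c))]

    @classmethod
    def linear_cancer_graph(
        cls,
        germline: list[SVEvent],
        trunk: list[SVEvent],
        subclone1: list[SVEvent],
        subclone2: list[SVEvent],
    ) -> "CloneGraph":
        """The four-population layout: normal -> trunk -> two sub-clones."""
        return cls(
            private={
                "normal": germline,
                "trunk": trunk,
                "subclone1": subclone1,
                "subclone2": subclone2,
            },
            parent={
                "normal": None,
                "trunk": "normal",
                "subclone1": "trunk",
                "subclone2": "trunk",
            },
        )


@dataclass
class MixtureSpec:
    """Cell-fraction mixture of clones; fractions must sum to 1."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()))
        if np.any(vals < 0):
            raise ValueError("mixture fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {vals.sum()}, not 1")

    # Preset mixtures for the benchmark scenarios: pure populations
    # (samples 1-4), high tumor content (5), low tumor content with one
    # sub-clone (6) and with two sub-clones (7).
    @classmethod
    def pure(cls, clone: str) -> "MixtureSpec":
        return cls({clone: 1.0})

    @classmethod
    def sample5(cls) -> "MixtureSpec":
        return cls({"normal": 0.2, "trunk": 0.8})

    @classmethod
    def sample6(cls) -> "MixtureSpec":
        return cls({"normal": 0.7, "trunk": 0.15, "subclone1": 0.15})

    @classmethod
    def sample7(cls) -> "MixtureSpec":
        return cls({"normal": 0.7, "trunk": 0.1, "subclone1": 0.1, "subclone2": 0.1})

    def expected_support_fraction(self, graph: CloneGraph, sv: SVEvent) -> float:
        """Sum over clones of cell fraction x allele dosage / ploidy."""
        frac = 0.0
        for clone, p in self.proportions.items():
            carried = any(e.sv_id == sv.sv_id for e in graph.sv_set(clone))
            if carried:
                frac += p * sv.dosage() / 2.0
        return frac


@dataclass
class NoiseModel:
    """Parametric measurement noise for simulated molecules.

    ``sizing_sd_per_kb`` is the Gaussian sd (bp) of a 1 kb inter-label
    distance; the sd of a distance ``d`` scales as ``sqrt(d / 1000)``.
    ``false_label_rate`` is the expected number of false labels per 100 kb
    (Poisson).  Molecule lengths are lognormal with a hard minimum.
    """

    sizing_sd_per_kb: float = 150.0
    stretch_range: tuple[float, float] = (0.97, 1.03)
    label_miss_prob: float = 0.10
    false_label_rate: float = 1.0
    length_log_mean: float = float(np.log(180_000.0))
    length_log_sd: float = 0.35
    min_length_bp: float = 80_000.0
    coverage: float = 100.0
    chimera_rate: float = 0.0  # present for completeness; off by default

    def __post_init__(self) -> None:
        if not 0 <= self.label_miss_prob <= 1:
            raise ValueError("label_miss_prob must be in [0, 1]")
        if self.sizing_sd_per_kb < 0 or self.false_label_rate < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        lo, hi = self.stretch_range
        if not (0 < lo <= hi):
            raise ValueError("invalid stretch_range")

    @classmethod
    def noise_free(cls, coverage: float = 100.0) -> "NoiseModel":
        return cls(
            sizing_sd_per_kb=0.0,
            stretch_range=(1.0, 1.0),
            label_miss_prob=0.0,
            false_label_rate=0.0,
            coverage=coverage,
        )

    def interval_sd(self, distance_bp: np.ndarray) -> np.ndarray:
        return self.sizing_sd_per_kb * np.sqrt(np.maximum(distance_bp, 0.0) / 1000.0)


@dataclass
class TruthRecord:
    """Ground truth for one simulated SV in one dataset."""

    sv: SVEvent
    expected_support_fraction: float
    ref_id: str
    start_bp: float
    end_bp: float
    origin_clone: str
    # per (clone, hap) witness interval used for empirical support counting:
    # (derived_map_id, lo, hi, carrier)
    witnesses: dict[tuple[str, int], tuple[str, float, float, bool]] = field(
        default_factory=dict
    )
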