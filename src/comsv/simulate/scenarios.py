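"""Toy references and randomized SV scenarios for benchmarking.

The default test reference is a small random genome labeled at roughly the
density of a nicking enzyme (~10 labels / 100 kb); DLS-like density (~16)
is available via ``labels_per_100kb``.
"""
from __future__ import annotations

import numpy as np

from ..formats.maps import LabelMap
from .events import CloneGraph, SVEvent

__all__ = [
    "toy_reference",
    "random_sv_events",
    "random_cancer_graph",
    "DEFAULT_SIZE_RANGES",
]

DEFAULT_SIZE_RANGES: dict[str, tuple[float, float]] = {
    "insertion": (2_500, 20_000),
    "deletion": (2_500, 20_000),
    "inversion": (60_000, 150_000),
    "duplication": (20_000, 40_000),
    "translocation_intra": (250_000, 350_000),
}


def toy_reference(
    seed: int | np.random.Generator = 0,
    n_chromosomes: int = 2,
    chromosome_length: float = 5e6,
    labels_per_100kb: float = 10.0,
) -> dict[str, LabelMap]:
    """Random reference label maps with exponential inter-label spacing."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    density = labels_per_100kb / 1e5
    refs: dict[str, LabelMap] = {}
    for c in range(1, n_chromosomes + 1):
        n_approx = int(chromosome_length * density * 1.5)
        gaps = rng.exponential(1.0 / density, n_approx)
        pos = np.cumsum(gaps)
        pos = pos[pos < chromosome_length - 1]
        refs[f"chr{c}"] = LabelMap(f"chr{c}", chromosome_length, pos)
    return refs


def _labels_in(ref: LabelMap, lo: float, hi: float) -> int:
    return int(
        np.searchsorted(ref.positions, hi, "left")
        - np.searchsorted(ref.positions, lo, "left")
    )


def _overlaps(occupied: list[tuple[str, float, float]], ref_id: str, lo: float, hi: float) -> bool:
    return any(r == ref_id and lo < b and a < hi for r, a, b in occupied)


def random_sv_events(
    rng: np.random.Generator,
    ref_maps: dict[str, LabelMap],
    counts: dict[str, int],
    origin_clone: str,
    occupied: list[tuple[str, float, float]],
    size_ranges: dict[str, tuple[float, float]] | None = None,
    zygosity: str = "mix",
    margin_bp: float = 60_000.0,
    prefix: str = "sv",
) -> list[SVEvent]:
    """Place non-overlapping random SVs, reserving a margin around each.

    ``occupied`` is shared across calls so that events from different clone
    stages never collide on any haplotype.  ``zygosity`` is ``het``, ``hom``
    or ``mix`` (random het/hom per event).
    """
    size_ranges = {**DEFAULT_SIZE_RANGES, **(size_ranges or {})}
    chrom_ids = sorted(ref_maps)
    lens = np.array([ref_maps[c].length_bp for c in chrom_ids])
    events: list[SVEvent] = []
    serial = 0

    def _zyg() -> tuple[str, int]:
        if zygosity == "mix":
            z = "hom" if rng.random() < 0.5 else "het"
        else:
            z = zygosity
        return z, int(rng.integers(2))

    # place the greediest events first (translocation tails reserve the most)
    order = [
        "translocation_inter", "translocation_intra", "inversion",
        "duplication", "deletion", "insertion",
    ]
    for sv_type in sorted(counts, key=lambda t: order.index(t) if t in order else 99):
        n = counts[sv_type]
        for _ in range(n):
            placed = False
            for _attempt in range(2000):
                if sv_type == "translocation_inter":
                    ca, cb = rng.choice(len(chrom_ids), 2, replace=False)
                    ra, rb = chrom_ids[ca], chrom_ids[cb]
                    pos_a = float(rng.uniform(0.75, 0.9) * lens[ca])
                    pos_b = float(rng.uniform(0.75, 0.9) * lens[cb])
                    if _overlaps(occupied, ra, pos_a - margin_bp, lens[ca]) or _overlaps(
                        occupied, rb, pos_b - margin_bp, lens[cb]
                    ):
                        continue
                    z, hap = _zyg()
                    sv = SVEvent(
                        sv_id=f"{prefix}_{origin_clone}_{sv_type}_{serial}",
                        sv_type=sv_type, ref_id=ra, start_bp=pos_a, end_bp=pos_a,
                        size_bp=0.0, zygosity=z, hap=hap, origin_clone=origin_clone,
                        dest_ref_id=rb, dest_bp=pos_b,
                    )
                    occupied.append((ra, pos_a - margin_bp, float(lens[ca])))
                    occupied.append((rb, pos_b - margin_bp, float(lens[cb])))
                    events.append(sv)
                    serial += 1
                    placed = True
                    break

                ci = int(rng.choice(len(chrom_ids), p=lens / lens.sum()))
                cid = chrom_ids[ci]
                ref = ref_maps[cid]
                lo_size, hi_size = size_ranges[sv_type]
                size = float(np.exp(rng.uniform(np.log(lo_size), np.log(hi_size))))
                span = 0.0 if sv_type == "insertion" else size
                start = float(rng.uniform(margin_bp, ref.length_bp - margin_bp - span))
                end = start + span
                if _overlaps(occupied, cid, start - margin_bp, end + margin_bp):
                    continue
                if sv_type in ("inversion", "duplication") and _labels_in(ref, start, end) < 3:
                    continue
                dest_ref_id = dest_bp = None
                reserve = [(cid, start - margin_bp, end + margin_bp)]
                if sv_type == "translocation_intra":
                    offset = float(rng.uniform(6e5, 1.2e6)) * (1 if rng.random() < 0.5 else -1)
                    dest_bp = start + offset if offset > 0 else start + offset
                    dest_bp = float(np.clip(dest_bp, margin_bp, ref.length_bp - margin_bp))
                    if start - margin_bp < dest_bp < end + margin_bp:
                        continue
                    if _overlaps(occupied, cid, dest_bp - margin_bp, dest_bp + margin_bp):
                        continue
                    dest_ref_id = cid
                    reserve.append((cid, dest_bp - margin_bp, dest_bp + margin_bp))
                novel = None
                if sv_type == "insertion":
                    density = ref.n_labels / ref.length_bp
                    gaps = rng.exponential(1.0 / density, max(4, int(size * density * 3)))
                    offs = np.cumsum(gaps)
                    novel = offs[offs < size]
                z, hap = _zyg()
                events.append(
                    SVEvent(
                        sv_id=f"{prefix}_{origin_clone}_{sv_type}_{serial}",
                        sv_type=sv_type, ref_id=cid, start_bp=start, end_bp=end,
                        size_bp=size, zygosity=z, hap=hap, origin_clone=origin_clone,
                        dest_ref_id=dest_ref_id, dest_bp=dest_bp,
                        novel_label_offsets=novel,
                    )
                )
                occupied.extend(reserve)
                serial += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {sv_type} after 2000 attempts; genome too full"
                )
    return events


def random_cancer_graph(
    rng: np.random.Generator,
    ref_maps: dict[str, LabelMap],
    stage_counts: dict[str, dict[str, int]],
    zygosity: str = "mix",
    size_ranges: dict[str, tuple[float, float]] | None = None,
) -> CloneGraph:
    """Build the normal -> trunk -> {subclone1, subclone2} evolution graph.

    ``stage_counts`` maps each stage name to its per-type private SV counts,
    e.g. ``{"normal": {"deletion": 5}, "trunk": {...}, ...}``.
    """
    occupied: list[tuple[str, float, float]] = []
    stages = {}
    for stage in ("normal", "trunk", "subclone1", "subclone2"):
        stages[stage] = random_sv_events(
            rng, ref_maps, stage_counts.get(stage, {}), origin_clone=stage,
            occupied=occupied, zygosity=zygosity, size_ranges=size_ranges,
        )
    return CloneGraph.linear_cancer_graph(
        stages["normal"], stages["trunk"], stages["subclone1"], stages["subclone2"]
    )
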