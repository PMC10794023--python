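"""Noisy molecule sampling from clone mixtures, with truth output.

Molecules are drawn clone-proportionally until the requested fold coverage of
the haploid reference is reached.  Each molecule gets a random haplotype,
start and lognormal length; its labels are thinned by the miss probability,
perturbed by Gaussian sizing error on every inter-label gap, salted with
Poisson false labels and scaled by a per-molecule stretch factor.  The true
alignments record the noise-free correspondence of the surviving true labels
to reference label sites, split into segments wherever the correspondence is
discontinuous (orientation flip, reference jump, non-monotone site order).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..formats.maps import AlignmentRecord, LabelMap
from .events import CloneGraph, MixtureSpec, NoiseModel, SVEvent, TruthRecord
from .genome import HaplotypeGenome, build_clone_genomes, project_position

__all__ = [
    "MoleculeMeta",
    "SimulatedDataset",
    "sample_molecules",
    "make_support_series",
    "empirical_support",
]

# A true alignment is split when the collinearity discrepancy between two
# consecutive true labels exceeds this; smaller discrepancies (plain indels)
# stay within one alignment record, mirroring what an aligner would emit.
SPLIT_GAP_BP = 50_000.0

WITNESS_MARGIN_BP = 1_000.0


@dataclass
class MoleculeMeta:
    molecule_id: str
    clone: str
    hap: int
    map_id: str
    start_bp: float
    length_bp: float
    stretch: float


@dataclass
class SimulatedDataset:
    molecules: list[LabelMap]
    true_alignments: list[AlignmentRecord]
    truth: list[TruthRecord]
    meta: list[MoleculeMeta]
    genomes: dict[tuple[str, int], HaplotypeGenome]
    ref_maps: dict[str, LabelMap]
    graph: CloneGraph
    mixture: MixtureSpec
    noise: NoiseModel

    def molecules_by_id(self) -> dict[str, LabelMap]:
        return {m.map_id: m for m in self.molecules}


def _witnesses_for_sv(
    sv: SVEvent,
    genomes: dict[tuple[str, int], HaplotypeGenome],
    margin: float = WITNESS_MARGIN_BP,
) -> dict[tuple[str, int], tuple[str, float, float, bool]]:
    """Derived-coordinate interval a molecule must span to inform on ``sv``."""
    # witness intervals have identical length (2 * margin) in every genome so
    # that molecule-length bias cancels and the empirical supporting fraction
    # is an unbiased estimate of sum(clone fraction * dosage / ploidy)
    out: dict[tuple[str, int], tuple[str, float, float, bool]] = {}
    for key, genome in genomes.items():
        carrier = sv.sv_id in genome.sv_ids
        chrom = sv.ref_id
        if carrier:
            bnds = genome.boundaries[chrom].get(sv.sv_id)
            if not bnds:
                continue
            if sv.sv_type == "insertion":
                center = 0.5 * (bnds[0] + bnds[1])  # middle of the insert
            else:
                center = bnds[0]  # the junction the SV creates
            lo, hi = center - margin, center + margin
        else:
            pieces = genome.pieces[chrom]
            if sv.sv_type == "deletion":
                anchor = 0.5 * (sv.start_bp + sv.end_bp)
            elif sv.sv_type == "duplication":
                anchor = sv.end_bp
            else:
                anchor = sv.start_bp
            d = project_position(pieces, chrom, anchor)
            if d is None:
                continue
            lo, hi = d - margin, d + margin
        out[key] = (chrom, lo, hi, carrier)
    return out


def make_truth(
    graph: CloneGraph,
    mixture: MixtureSpec,
    genomes: dict[tuple[str, int], HaplotypeGenome],
) -> list[TruthRecord]:
    records = []
    for sv in graph.all_events():
        frac = mixture.expected_support_fraction(graph, sv)
        if frac <= 0:
            continue
        records.append(
            TruthRecord(
                sv=sv,
                expected_support_fraction=frac,
                ref_id=sv.ref_id,
                start_bp=sv.start_bp,
                end_bp=sv.end_bp,
                origin_clone=sv.origin_clone,
                witnesses=_witnesses_for_sv(sv, genomes),
            )
        )
    return records


def _true_alignment_runs(
    rel_true: np.ndarray,
    src_ref: np.ndarray,
    src_pos: np.ndarray,
    src_site: np.ndarray,
    strand: np.ndarray,
) -> list[list[int]]:
    """Indices (into the survivor arrays) of each collinear alignment run."""
    runs: list[list[int]] = []
    cur: list[int] = []
    for i in range(rel_true.size):
        if src_site[i] < 0:  # novel label: unaligned, breaks nothing by itself
            continue
        if not cur:
            cur = [i]
            continue
        j = cur[-1]
        ok = src_ref[i] == src_ref[j] and strand[i] == strand[j]
        if ok:
            step = (src_site[i] - src_site[j]) * strand[i]
            ok = step > 0
        if ok:
            expected = (src_pos[i] - src_pos[j]) * strand[i]
            observed = rel_true[i] - rel_true[j]
            ok = abs(expected - observed) <= SPLIT_GAP_BP
        if ok:
            cur.append(i)
        else:
            if len(cur) >= 2:
                runs.append(cur)
            cur = [i]
    if len(cur) >= 2:
        runs.append(cur)
    return runs


def sample_molecules(
    clone_genomes: dict[tuple[str, int], HaplotypeGenome],
    graph: CloneGraph,
    mixture: MixtureSpec,
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
    ref_maps: dict[str, LabelMap] | None = None,
) -> SimulatedDataset:
    """Draw noisy molecules from a clone mixture; emit truth and alignments."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = [(c, p) for c, p in mixture.proportions.items() if p > 0]
    if not active:
        raise ValueError("mixture has no clones with positive fraction")
    keys = [(c, h) for c, _ in active for h in (0, 1)]
    probs = np.array([p / 2.0 for _, p in active for _ in (0, 1)])
    probs /= probs.sum()
    for key in keys:
        if key not in clone_genomes:
            raise ValueError(f"mixture clone {key[0]} missing from clone_genomes")

    if ref_maps is None:  # fall back to the first genome's chromosome set
        ref_maps = dict(clone_genomes[keys[0]].maps)
    haploid_len = sum(m.length_bp for m in ref_maps.values())
    target_bp = noise.coverage * haploid_len

    molecules: list[LabelMap] = []
    alignments: list[AlignmentRecord] = []
    meta: list[MoleculeMeta] = []
    total_bp = 0.0
    idx = 0
    while total_bp < target_bp:
        gkey = keys[rng.choice(len(keys), p=probs)]
        genome = clone_genomes[gkey]
        chrom_ids = list(genome.maps)
        lens = np.array([genome.maps[c].length_bp for c in chrom_ids])
        cid = chrom_ids[rng.choice(len(chrom_ids), p=lens / lens.sum())]
        cmap = genome.maps[cid]
        lift = genome.lifts[cid]
        length = float(np.exp(rng.normal(noise.length_log_mean, noise.length_log_sd)))
        length = min(max(length, noise.min_length_bp), cmap.length_bp * 0.9)
        start = float(rng.uniform(0, cmap.length_bp - length))

        i0 = int(np.searchsorted(cmap.positions, start, side="left"))
        i1 = int(np.searchsorted(cmap.positions, start + length, side="left"))
        rel = cmap.positions[i0:i1] - start
        keep = rng.random(rel.size) >= noise.label_miss_prob
        rel_k = rel[keep]
        sl = slice(i0, i1)
        src_ref = lift.src_ref[sl][keep]
        src_pos = lift.src_pos[sl][keep]
        src_site = lift.src_site[sl][keep]
        strand = lift.strand[sl][keep]

        gaps = np.diff(np.concatenate([[0.0], rel_k, [length]]))
        noisy = gaps + rng.normal(0.0, 1.0, gaps.size) * noise.interval_sd(gaps)
        noisy = np.maximum(noisy, 1.0)
        cum = np.cumsum(noisy)
        new_len = float(cum[-1])
        new_pts = cum[:-1]

        n_false = rng.poisson(noise.false_label_rate * new_len / 1e5)
        false_pts = rng.uniform(0.0, new_len, n_false)
        stretch = float(rng.uniform(*noise.stretch_range))
        all_pts = np.concatenate([new_pts, false_pts]) * stretch
        mol_len = new_len * stretch
        order = np.argsort(all_pts, kind="stable")
        sorted_pts = all_pts[order]
        # enforce strictly increasing positions (collisions are measure-zero)
        for k in range(1, sorted_pts.size):
            if sorted_pts[k] <= sorted_pts[k - 1]:
                sorted_pts[k] = sorted_pts[k - 1] + 1e-3
        mol_id = f"mol{idx:06d}"
        molecules.append(LabelMap(mol_id, mol_len, sorted_pts))

        # 1-based final label index of each surviving true label
        final_index = np.empty(all_pts.size, dtype=int)
        final_index[order] = np.arange(1, all_pts.size + 1)
        true_final = final_index[: new_pts.size]

        for run in _true_alignment_runs(rel_k, src_ref, src_pos, src_site, strand):
            run_strand = int(strand[run[0]])
            pairs_mol_order = [(int(src_site[i]), int(true_final[i])) for i in run]
            if run_strand > 0:
                pairs = pairs_mol_order
                orientation = "+"
            else:
                pairs = list(reversed(pairs_mol_order))
                orientation = "-"
            ref_positions = [float(src_pos[i]) for i in run]
            q_positions = [float(sorted_pts[true_final[i] - 1]) for i in run]
            if run_strand > 0:
                ref_start, ref_end = ref_positions[0], ref_positions[-1]
                q_start, q_end = q_positions[0], q_positions[-1]
            else:
                ref_start, ref_end = ref_positions[-1], ref_positions[0]
                q_start, q_end = q_positions[-1], q_positions[0]
            alignments.append(
                AlignmentRecord(
                    query_id=mol_id,
                    ref_id=str(src_ref[run[0]]),
                    orientation=orientation,
                    query_start_bp=q_start,
                    query_end_bp=q_end,
                    ref_start_bp=ref_start,
                    ref_end_bp=ref_end,
                    site_pairs=pairs,
                    confidence=15.0,
                )
            )

        meta.append(
            MoleculeMeta(mol_id, genome.clone, genome.hap, cid, start, length, stretch)
        )
        total_bp += length
        idx += 1

    truth = make_truth(graph, mixture, clone_genomes)
    return SimulatedDataset(
        molecules=molecules,
        true_alignments=alignments,
        truth=truth,
        meta=meta,
        genomes=clone_genomes,
        ref_maps=ref_maps,
        graph=graph,
        mixture=mixture,
        noise=noise,
    )


def empirical_support(dataset: SimulatedDataset) -> list[tuple[TruthRecord, int, int]]:
    """Count SV-supporting vs spanning molecules at every truth locus."""
    out = []
    for t in dataset.truth:
        n = k = 0
        for m in dataset.meta:
            w = t.witnesses.get((m.clone, m.hap))
            if w is None:
                continue
            map_id, lo, hi, carrier = w
            if m.map_id == map_id and m.start_bp <= lo and m.start_bp + m.length_bp >= hi:
                n += 1
                k += int(carrier)
        out.append((t, k, n))
    return out


def make_support_series(
    ref_maps: dict[str, LabelMap],
    sv_events: list[SVEvent],
    fractions: list[float],
    noise: NoiseModel,
    seed: int = 0,
) -> list[SimulatedDataset]:
    """One dataset per requested supporting fraction.

    The SVs are made homozygous in a single 'tumor' clone mixed with a normal
    clone, so that the expected supporting fraction at every locus equals the
    mixture's tumor fraction exactly.
    """
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fractions must be in (0, 1], got {f}")
    base = [
        SVEvent(
            sv_id=sv.sv_id, sv_type=sv.sv_type, ref_id=sv.ref_id,
            start_bp=sv.start_bp, end_bp=sv.end_bp, size_bp=sv.size_bp,
            zygosity="hom", origin_clone="tumor", dest_ref_id=sv.dest_ref_id,
            dest_bp=sv.dest_bp, novel_label_offsets=sv.novel_label_offsets,
        )
        for sv in sv_events
    ]
    graph = CloneGraph(
        private={"normal": [], "tumor": base},
        parent={"normal": None, "tumor": "normal"},
    )
    genomes = build_clone_genomes(ref_maps, graph)
    root = np.random.default_rng(seed)
    datasets = []
    for f in fractions:
        mixture = MixtureSpec({"normal": 1.0 - f, "tumor": f} if f < 1 else {"tumor": 1.0})
        datasets.append(
            sample_molecules(
                genomes, graph, mixture, noise, seed=root.spawn(1)[0], ref_maps=ref_maps
            )
        )
    return datasets
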