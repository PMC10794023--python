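"""Break-point consolidation: cluster junction calls across molecules and
contigs, refine positions, and promote complementary clusters to complete
SVs (partial when only one side of an event is seen).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..calls import SVCall
from .junctions import BreakPointCall, ComplexParams, FullSpanRecord

__all__ = ["BreakPointCluster", "ComplexSVCall", "cluster_breakpoints",
           "consolidate_breakpoints"]


@dataclass
class BreakPointCluster:
    inferred_type: str
    ref_a: str
    ref_b: str
    pattern: str
    pos_a: float
    pos_b: float
    members: list[BreakPointCall]
    molecule_support: set[str] = field(default_factory=set)
    contig_support: set[str] = field(default_factory=set)
    full_span: int = 0
    unit: tuple[float, float] | None = None
    size_bp: float = 0.0

    def effective_support(self, params: ComplexParams) -> int:
        n = len(self.molecule_support)
        if self.contig_support:
            n += params.contig_weight if n >= 1 else 1
        return n


@dataclass
class ComplexSVCall:
    sv_type: str  # inversion | duplication | translocation_intra | translocation_inter
    ref_id: str
    start_bp: float
    end_bp: float
    ref_id_b: str | None
    pos_b: float | None
    status: str  # complete | partial
    support_by_breakpoint: list[int]
    full_span_support: int
    supporting_molecules: list[str]
    confidence: float = 0.0
    size_bp: float = 0.0


def _weighted_median(values: list[float], weights: list[float]) -> float:
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, cum[-1] / 2.0)])


def cluster_breakpoints(
    calls: list[BreakPointCall], params: ComplexParams | None = None
) -> list[BreakPointCluster]:
    """Greedy 1-D clustering of break-point calls of the same type/pattern."""
    params = params or ComplexParams()
    buckets: dict[tuple, list[BreakPointCall]] = {}
    for c in calls:
        key = (c.inferred_type, c.locus_a[0], c.locus_b[0], c.pattern)
        buckets.setdefault(key, []).append(c)
    clusters: list[BreakPointCluster] = []
    for (itype, ref_a, ref_b, pattern), bucket in sorted(buckets.items()):
        bucket.sort(key=lambda c: (c.locus_a[1], c.locus_b[1]))
        current: list[BreakPointCall] = []
        for c in bucket:
            if current and (
                abs(c.locus_a[1] - current[-1].locus_a[1]) > params.merge_window_bp
                or abs(c.locus_b[1] - current[-1].locus_b[1]) > params.merge_window_bp
            ):
                clusters.append(_finish_cluster(itype, ref_a, ref_b, pattern, current, params))
                current = []
            current.append(c)
        if current:
            clusters.append(_finish_cluster(itype, ref_a, ref_b, pattern, current, params))
    return clusters


def _finish_cluster(
    itype: str, ref_a: str, ref_b: str, pattern: str,
    members: list[BreakPointCall], params: ComplexParams,
) -> BreakPointCluster:
    weights = [
        float(params.contig_weight) if m.source == "contig" else 1.0 for m in members
    ]
    pos_a = _weighted_median([m.locus_a[1] for m in members], weights)
    pos_b = _weighted_median([m.locus_b[1] for m in members], weights)
    mols = {m.support[0] for m in members if m.source != "contig"}
    ctgs = {m.support[0] for m in members if m.source == "contig"}
    units = [m.unit for m in members if m.unit is not None]
    unit = None
    if units:
        unit = (
            float(np.median([u[0] for u in units])),
            float(np.median([u[1] for u in units])),
        )
    sizes = [m.size_bp for m in members if m.size_bp]
    return BreakPointCluster(
        itype, ref_a, ref_b, pattern, pos_a, pos_b, members,
        molecule_support=mols, contig_support=ctgs,
        full_span=sum(m.full_span for m in members),
        unit=unit,
        size_bp=float(np.median(sizes)) if sizes else 0.0,
    )


def _confidence(support: int, complete: bool, params: ComplexParams) -> float:
    z = (support - params.confidence_halfpoint) / 2.0 + (0.5 if complete else 0.0)
    return float(1.0 / (1.0 + np.exp(-z)))


def consolidate_breakpoints(
    calls: list[BreakPointCall],
    full_span: list[FullSpanRecord] | None = None,
    params: ComplexParams | None = None,
) -> tuple[list[ComplexSVCall], list[SVCall]]:
    """Pair complementary break-point clusters into complex SV calls.

    Returns ``(complex_calls, junction_indels)``: large junction-implied
    indels are emitted separately so the downstream annotation step can
    reconcile them with the indel pipeline's namespace.
    """
    params = params or ComplexParams()
    full_span = full_span or []
    clusters = [
        c for c in cluster_breakpoints(calls, params)
        if c.effective_support(params) >= params.min_bp_support
        or (c.contig_support and not c.molecule_support)
    ]
    complex_calls: list[ComplexSVCall] = []
    junction_indels: list[SVCall] = []

    def _full_count(sv_type: str, ref: str, lo: float, hi: float) -> tuple[int, list[str]]:
        n = 0
        mols = []
        for fs in full_span:
            if fs.sv_type != sv_type:
                continue
            if any(r == ref and abs(p - lo) <= params.pair_window_bp for r, p in fs.loci) or \
               any(r == ref and abs(p - hi) <= params.pair_window_bp for r, p in fs.loci):
                n += 1
                mols.append(fs.molecule_id)
        return n, mols

    def _components(
        items: list[BreakPointCluster], linked
    ) -> list[list[BreakPointCluster]]:
        parent = list(range(len(items)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if linked(items[i], items[j]):
                    parent[find(i)] = find(j)
        comps: dict[int, list[BreakPointCluster]] = {}
        for i, c in enumerate(items):
            comps.setdefault(find(i), []).append(c)
        return list(comps.values())

    def _both_loci_close(a: BreakPointCluster, b: BreakPointCluster) -> bool:
        return (
            a.ref_a == b.ref_a and a.ref_b == b.ref_b
            and abs(a.pos_a - b.pos_a) <= params.pair_window_bp
            and abs(a.pos_b - b.pos_b) <= params.pair_window_bp
        )

    def _any_locus_close(a: BreakPointCluster, b: BreakPointCluster) -> bool:
        if a.ref_a != b.ref_a:
            return False
        return any(
            abs(x - y) <= params.pair_window_bp
            for x in (a.pos_a, a.pos_b)
            for y in (b.pos_a, b.pos_b)
        )

    def _comp_stats(comp: list[BreakPointCluster]):
        mols = set().union(*(c.molecule_support for c in comp))
        ctgs = set().union(*(c.contig_support for c in comp))
        weights = [len(c.molecule_support) + len(c.contig_support) for c in comp]
        return mols, ctgs, weights

    # ---- inversions: one event = the two boundary-junction flavours (+- / -+)
    inv = [c for c in clusters if c.inferred_type == "inversion_bp"]
    for comp in _components(inv, _both_loci_close):
        patterns = {c.pattern for c in comp}
        mols, ctgs, weights = _comp_stats(comp)
        lo = float(np.mean([c.pos_a for c in comp]))
        hi = float(np.mean([c.pos_b for c in comp]))
        nfs, fs_mols = _full_count("inversion", comp[0].ref_a, lo, hi)
        complete = len(patterns) >= 2 or nfs >= 1
        support = len(mols | ctgs)
        complex_calls.append(
            ComplexSVCall(
                "inversion", comp[0].ref_a, lo, hi, None, None,
                "complete" if complete else "partial",
                weights, nfs, sorted(mols | ctgs | set(fs_mols)),
                _confidence(support, complete, params), size_bp=hi - lo,
            )
        )

    # ---- duplications: the junction carries the unit span; complete when a
    # molecule covers beyond both unit boundaries (second-copy full span)
    dup = [c for c in clusters if c.inferred_type == "dup_bp"]
    for comp in _components(dup, _both_loci_close):
        mols, ctgs, weights = _comp_stats(comp)
        # molecules not spanning the whole unit under-estimate it, so prefer
        # full-span members, else take the widest observed overlap
        full_units = [
            m.unit for c in comp for m in c.members
            if m.unit is not None and m.full_span
        ]
        units = full_units or [c.unit for c in comp if c.unit is not None]
        if units:
            unit = (
                float(np.median([u[0] for u in units])),
                float(np.median([u[1] for u in units])),
            )
        else:
            unit = (comp[0].pos_a, comp[0].pos_b)
        nfull = sum(c.full_span for c in comp)
        complete = nfull >= 1
        support = len(mols | ctgs)
        complex_calls.append(
            ComplexSVCall(
                "duplication", comp[0].ref_a, unit[0], unit[1], None, None,
                "complete" if complete else "partial",
                weights, nfull, sorted(mols | ctgs),
                _confidence(support, complete, params),
                size_bp=unit[1] - unit[0],
            )
        )

    # ---- inter translocations: a balanced event shows two reciprocal
    # junction flavours (query order A->B and B->A) at the same locus pair
    tra = [c for c in clusters if c.inferred_type == "tra_inter_bp"]
    for comp in _components(tra, _both_loci_close):
        patterns = {c.pattern for c in comp}
        mols, ctgs, weights = _comp_stats(comp)
        pos_a = float(np.mean([c.pos_a for c in comp]))
        pos_b = float(np.mean([c.pos_b for c in comp]))
        nfs, fs_mols = _full_count("translocation_inter", comp[0].ref_a, pos_a, pos_a)
        complete = len(patterns) >= 2 or nfs >= 1
        support = len(mols | ctgs)
        complex_calls.append(
            ComplexSVCall(
                "translocation_inter", comp[0].ref_a, pos_a, pos_a,
                comp[0].ref_b, pos_b,
                "complete" if complete else "partial",
                weights, nfs, sorted(mols | ctgs | set(fs_mols)),
                _confidence(support, complete, params),
            )
        )

    # ---- intra translocations: the excision and the two destination
    # junctions share loci pairwise; a chain seeing >= 2 junctions is complete
    intra = [c for c in clusters if c.inferred_type == "tra_intra_bp"]
    for comp in _components(intra, _any_locus_close):
        pts = sorted(p for c in comp for p in (c.pos_a, c.pos_b))
        mols, ctgs, weights = _comp_stats(comp)
        nfs, fs_mols = _full_count("translocation_intra", comp[0].ref_a, pts[0], pts[-1])
        complete = len(comp) >= 2 or nfs >= 1
        complex_calls.append(
            ComplexSVCall(
                "translocation_intra", comp[0].ref_a, pts[0], pts[-1],
                comp[0].ref_a, pts[-1],
                "complete" if complete else "partial",
                weights, nfs, sorted(mols | ctgs | set(fs_mols)),
                _confidence(len(mols | ctgs), complete, params),
                size_bp=pts[-1] - pts[0],
            )
        )

    # ---- junction-implied large indels -> indel namespace
    serial = 0
    for c in clusters:
        if c.inferred_type not in ("large_del_bp", "large_ins_bp"):
            continue
        sv_type = "deletion" if c.inferred_type == "large_del_bp" else "insertion"
        support = len(c.molecule_support) + len(c.contig_support)
        junction_indels.append(
            SVCall(
                call_id=f"junction_indel_{serial}",
                sv_type=sv_type,
                ref_id=c.ref_a,
                start_bp=c.pos_a,
                end_bp=c.pos_b if sv_type == "deletion" else c.pos_a,
                size_bp=c.size_bp,
                support=support,
                total=support,
                allele_fraction=float("nan"),
                status="complete",
                confidence=_confidence(support, True, params),
                source="complex-junction",
                supporting_molecules=sorted(c.molecule_support | c.contig_support),
            )
        )
        serial += 1
    complex_calls.sort(key=lambda c: (c.ref_id, c.start_bp, c.sv_type))
    return complex_calls, junction_indels
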