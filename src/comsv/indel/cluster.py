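"""One-dimensional model-based clustering of pooled spanning distances.

The number of alleles at a candidate region is found by maximizing a
penalized classification likelihood over all contiguous partitions of the
sorted distances into k in {1..max_k} groups:

    criterion(partition) = sum_g [ log N(x_i | mu_g, max(sd_g, sd_floor))
                                   + n_g * log(n_g / n) ]
                           - 0.5 * (3k - 1) * log(n)

subject to every group having at least ``min_cluster_size`` members and
adjacent group means being separated by at least ``min_separation_bp``
(k = 1 is always admissible).  No assumption is made about the proportion of
molecules supporting any allele.  Ties prefer smaller k, then the
lexicographically smallest split, making the output deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import IndelParams

__all__ = ["Cluster", "DistanceClustering", "cluster_distances", "partition_criterion"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Cluster:
    mean_bp: float
    sd_bp: float
    members: list[int]  # indices into the original observation order

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class DistanceClustering:
    clusters: list[Cluster]  # ordered by mean
    chosen_k: int
    criterion_values: dict[int, float] = field(default_factory=dict)


def _group_loglik(x_sorted: np.ndarray, i: int, j: int, n: int, sd_floor: float) -> float:
    g = x_sorted[i:j]
    ng = j - i
    mean = float(g.mean())
    var = float(g.var())
    sd = max(np.sqrt(var), sd_floor)
    ss = var * ng
    ll = -0.5 * ng * _LOG_2PI - ng * np.log(sd) - ss / (2.0 * sd * sd)
    ll += ng * np.log(ng / n)
    return float(ll)


def partition_criterion(
    x_sorted: np.ndarray, cuts: tuple[int, ...], params: IndelParams
) -> float:
    """Penalized criterion of a contiguous partition given by cut points.

    ``cuts`` are interior boundaries (group g is ``x_sorted[cuts[g-1]:cuts[g]]``
    with implicit 0 and n).  Returns ``-inf`` for partitions violating the
    minimum size or separation constraints (except k = 1, always allowed).
    """
    n = x_sorted.size
    bounds = (0, *cuts, n)
    k = len(bounds) - 1
    means = []
    total = 0.0
    for i, j in zip(bounds, bounds[1:]):
        if j - i <= 0:
            return -np.inf
        if k > 1 and j - i < params.min_cluster_size:
            return -np.inf
        means.append(float(x_sorted[i:j].mean()))
        total += _group_loglik(x_sorted, i, j, n, params.sd_floor_bp)
    if k > 1 and np.any(np.diff(means) < params.min_separation_bp):
        return -np.inf
    total -= 0.5 * (3 * k - 1) * np.log(n)
    return total


def cluster_distances(
    observations: np.ndarray | list[float],
    params: IndelParams | None = None,
) -> DistanceClustering:
    """Cluster 1-D distances; see the module docstring for the model."""
    params = params or IndelParams()
    x = np.asarray(observations, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("cannot cluster zero observations")
    order = np.argsort(x, kind="stable")
    xs = x[order]

    best_cuts: tuple[int, ...] = ()
    best_val = partition_criterion(xs, (), params)
    crit: dict[int, float] = {1: best_val}
    mcs = params.min_cluster_size
    if params.max_k >= 2:
        best2 = -np.inf
        for c in range(mcs, n - mcs + 1):
            v = partition_criterion(xs, (c,), params)
            if v > best2 + 1e-12:
                best2 = v
                if v > best_val + 1e-12:
                    best_val, best_cuts = v, (c,)
        if best2 > -np.inf:
            crit[2] = best2
    if params.max_k >= 3:
        best3 = -np.inf
        for c1 in range(mcs, n - 2 * mcs + 1):
            for c2 in range(c1 + mcs, n - mcs + 1):
                v = partition_criterion(xs, (c1, c2), params)
                if v > best3 + 1e-12:
                    best3 = v
                    if v > best_val + 1e-12:
                        best_val, best_cuts = v, (c1, c2)
        if best3 > -np.inf:
            crit[3] = best3

    bounds = (0, *best_cuts, n)
    clusters = []
    for i, j in zip(bounds, bounds[1:]):
        g = xs[i:j]
        clusters.append(
            Cluster(float(g.mean()), float(g.std()), [int(v) for v in order[i:j]])
        )
    return DistanceClustering(clusters, len(clusters), crit)
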