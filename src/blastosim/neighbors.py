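"""Neighbor graphs: 2D distance thresholds and the 3D halfway-point method.

In 2D, "nearest neighbors" for the developmental rules simply means all
cells within a contact radius (default 2.5 cell radii, the TE-TE cutoff).
In 3D a distance threshold confuses next-nearest with nearest neighbors, so
the halfway-point test is used instead: a candidate neighbor is kept only if
the midpoint of the connecting segment is not closer to some third cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .state import Embryo, Lineage

__all__ = [
    "NeighborGraph",
    "neighbor_graph_2d",
    "true_nearest_neighbors",
    "true_nearest_neighbors_3d",
    "rule_neighbor_graph",
    "count_lineage_neighbors",
]


@dataclass
class NeighborGraph:
    adjacency: dict[int, list[int]] = field(default_factory=dict)
    radius_used: float | None = None
    dimension: int = 2

    def neighbors(self, i: int) -> list[int]:
        return self.adjacency.get(i, [])

    def degree(self, i: int) -> int:
        return len(self.adjacency.get(i, []))


def neighbor_graph_from_points(points: np.ndarray, radius: float) -> NeighborGraph:
    """Symmetric distance-threshold graph (edge iff d <= radius)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    if n > 1:
        tree = cKDTree(points)
        for i, j in tree.query_pairs(r=radius):
            adjacency[i].append(j)
            adjacency[j].append(i)
    for v in adjacency.values():
        v.sort()
    return NeighborGraph(adjacency=adjacency, radius_used=radius,
                         dimension=points.shape[1] if n else 2)


def neighbor_graph_2d(embryo: Embryo, radius: float | None = None) -> NeighborGraph:
    """Contact graph of all living cells at the rule neighborhood radius."""
    if embryo.n == 0:
        raise ValueError("embryo has no living cells")
    r = embryo.params.neighbor_radius if radius is None else radius
    return neighbor_graph_from_points(embryo.positions, r)


def true_nearest_neighbors(points, rmax: float = 5.0) -> NeighborGraph:
    """Halfway-point true-nearest-neighbor graph in any dimension.

    Edge (i, j) iff d(i, j) <= rmax and no third cell lies strictly closer
    to the pair midpoint than the endpoints do.  This is the graph the
    interaction filter and the developmental rules use; it adapts to the
    local packing density (an interior cell in a plane has ~6 neighbors
    regardless of compression).
    """
    from . import _kernels

    points = np.ascontiguousarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    adj = np.zeros((n, n), dtype=np.uint8)
    lin = np.zeros(n, dtype=np.int8)
    _kernels.build_nn_adj(points, lin, n, points.shape[1], rmax, True, adj)
    adjacency = {i: [int(j) for j in np.flatnonzero(adj[i])] for i in range(n)}
    return NeighborGraph(adjacency=adjacency, radius_used=None,
                         dimension=points.shape[1])


def rule_neighbor_graph(embryo: Embryo) -> NeighborGraph:
    """Neighborhood graph used by Rules 1, 2 and 4."""
    if embryo.params.rule_neighbors == "nearest" and embryo.n >= 2:
        return true_nearest_neighbors(embryo.positions,
                                      rmax=embryo.params.global_cutoff)
    return neighbor_graph_2d(embryo)


def true_nearest_neighbors_3d(points, n_candidates: int = 20) -> NeighborGraph:
    """Halfway-point true-nearest-neighbor graph for a 3D point cloud.

    For each point, the ``n_candidates`` closest points by center distance
    are screened: a candidate is retained only if the halfway point of the
    connecting segment is at least as close to the two endpoints as to every
    other candidate (ties retained).  The result is symmetrized.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    tree = cKDTree(points)
    d_self, _ = tree.query(points, k=2)
    if np.any(d_self[:, 1] < 1e-9):
        raise ValueError("duplicate points")
    k = min(n_candidates + 1, n)
    dists, idx = tree.query(points, k=k)
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        cand = [j for j in np.atleast_1d(idx[i]) if j != i]
        for j in cand:
            mid = 0.5 * (points[i] + points[j])
            ref = np.linalg.norm(mid - points[i])
            keep = True
            for h in cand:
                if h == j:
                    continue
                if np.linalg.norm(mid - points[h]) < ref - 1e-12:
                    keep = False
                    break
            if keep:
                adjacency[i].add(j)
                adjacency[j].add(i)
    return NeighborGraph(
        adjacency={i: sorted(v) for i, v in adjacency.items()},
        radius_used=None, dimension=3)


_FILTERS = {
    "icm": lambda lg: lg in (Lineage.UNDETERMINED_ICM, Lineage.EPI, Lineage.PRE),
    "non_pre_icm": lambda lg: lg in (Lineage.UNDETERMINED_ICM, Lineage.EPI),
    "epi": lambda lg: lg == Lineage.EPI,
    "pre": lambda lg: lg == Lineage.PRE,
    "undetermined": lambda lg: lg == Lineage.UNDETERMINED_ICM,
    "te": lambda lg: lg == Lineage.TE,
    "any": lambda lg: True,
}


def count_lineage_neighbors(graph: NeighborGraph, embryo: Embryo, i: int,
                            lineage_filter) -> int:
    """Number of living neighbors of cell ``i`` matching the filter.

    ``lineage_filter`` is a predicate on :class:`Lineage` or one of the named
    filters: {'icm', 'non_pre_icm', 'epi', 'pre', 'undetermined', 'te', 'any'}.
    """
    if i not in graph.adjacency:
        raise KeyError(f"cell {i} not in graph")
    pred = _FILTERS[lineage_filter] if isinstance(lineage_filter, str) else lineage_filter
    return sum(1 for j in graph.neighbors(i) if pred(Lineage(int(embryo.lin[j]))))
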