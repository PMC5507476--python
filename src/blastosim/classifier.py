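"""Endpoint classification into success or the five failure categories.

A replicate is successful when (i) the TE circles form a closed shell
enclosing all ICM cells, (ii) a cavity (cell-free region of at least three
cell areas) exists with the ICM clustered to one side, (iii) the PrE lies
between cavity and EPI (every EPI cell is "sealed" from the cavity by the
PrE layer), and (iv) no PrE cell is buried in the EPI core.  Double PrE
layers count as success as long as they seal the EPI.

Failures map onto: NO_TE (no closed shell / no cavity), EPI_ONLY and
PRE_ONLY (single-lineage ICM; checked before the geometric criteria, since
the composition defect is the primary phenotype), EPI_IN_PRE_ERROR (PrE
layer fails to seal the EPI from the cavity), PRE_IN_EPI_ERROR (deep PrE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .lifecycle import deep_pre_indices
from .neighbors import rule_neighbor_graph
from .state import (Embryo, EmptyEmbryoError, Lineage, Outcome,
                    OutcomeCategory, biological_counts)

__all__ = ["EndpointDiagnostics", "classify", "diagnose", "ensemble_stats",
           "scale_2d_to_3d", "scale_3d_to_2d"]

#: Grid resolution (cell radii) for shell/cavity rasterization.
GRID_H = 0.5
#: TE barrier disc radius: half the TE-TE contact distance, so the discs of
#: two touching TE circles overlap and close the shell.
TE_BARRIER_RADIUS = 1.25
#: Clearance from the nearest cell center for a cavity seed point: an empty
#: disc of three cell areas (radius sqrt(3)) plus the unit cell radius.
CAVITY_CLEARANCE = 1.0 + math.sqrt(3.0)
#: Minimal distance between cavity center and ICM centroid ("one-sided").
ONE_SIDED_MIN_DIST = 2.0
#: An EPI cell is sealed if its segment to the cavity center passes within
#: this distance of a PrE cell.
SEAL_RADIUS = 1.0


@dataclass
class EndpointDiagnostics:
    te_shell_intact: bool = False
    cavity_present: bool = False
    icm_one_sided: bool = False
    pre_layer_seals_epi: bool = False
    misplaced_epi_in_pre: int = 0
    misplaced_pre_in_epi: int = 0
    pre_layer_count: int = 0
    cavity_center: np.ndarray | None = None


def _shell_and_cavity(pos: np.ndarray, te_mask: np.ndarray,
                      icm_mask: np.ndarray) -> tuple[bool, bool, bool, np.ndarray | None]:
    """Flood-fill test of shell closure, cavity existence and one-sidedness."""
    margin = 3.0
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    nx = int(np.ceil((hi[0] - lo[0]) / GRID_H)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / GRID_H)) + 1
    gx, gy = np.meshgrid(lo[0] + GRID_H * np.arange(nx),
                         lo[1] + GRID_H * np.arange(ny))
    grid_pts = np.column_stack([gx.ravel(), gy.ravel()])

    te_tree = cKDTree(pos[te_mask])
    d_te = te_tree.query(grid_pts)[0].reshape(ny, nx)
    free = d_te > TE_BARRIER_RADIUS

    # 4-connectivity so diagonal leaks do not pierce the barrier
    labels, _ = ndimage.label(free, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    border = np.concatenate([labels[0, :], labels[-1, :],
                             labels[:, 0], labels[:, -1]])
    outside = set(np.unique(border)) - {0}

    def node_label(p):
        ix = int(round((p[0] - lo[0]) / GRID_H))
        iy = int(round((p[1] - lo[1]) / GRID_H))
        ix = min(max(ix, 0), nx - 1)
        iy = min(max(iy, 0), ny - 1)
        return labels[iy, ix]

    icm_pos = pos[icm_mask]
    shell_intact = not any(node_label(p) in outside for p in icm_pos)

    all_tree = cKDTree(pos)
    d_all = all_tree.query(grid_pts)[0].reshape(ny, nx)
    interior = free & (labels > 0) & ~np.isin(labels, list(outside))
    cavity_present = False
    one_sided = False
    cavity_center = None
    if interior.any():
        d_int = np.where(interior, d_all, -np.inf)
        iy, ix = np.unravel_index(int(np.argmax(d_int)), d_int.shape)
        if d_int[iy, ix] >= CAVITY_CLEARANCE:
            cavity_present = True
            cavity_center = np.array([lo[0] + GRID_H * ix, lo[1] + GRID_H * iy])
            if len(icm_pos):
                icm_centroid = icm_pos.mean(axis=0)
                one_sided = (np.linalg.norm(cavity_center - icm_centroid)
                             >= ONE_SIDED_MIN_DIST)
    return shell_intact, cavity_present, one_sided, cavity_center


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return float(np.linalg.norm(p - a))
    s = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + s * ab)))


def _seal_test(pos, lin, cavity_center) -> tuple[bool, int, int]:
    """Check that every EPI (or undetermined) cell is screened from the
    cavity by the PrE layer.  Returns (sealed, n_unsealed, pre_layer_count)."""
    epi_idx = np.flatnonzero((lin == int(Lineage.EPI))
                             | (lin == int(Lineage.UNDETERMINED_ICM)))
    pre_pos = pos[lin == int(Lineage.PRE)]
    if cavity_center is None or len(epi_idx) == 0:
        return True, 0, 0
    if len(pre_pos) == 0:
        return False, len(epi_idx), 0
    unsealed = 0
    layer_counts = []
    for e in epi_idx:
        dists = [_point_segment_distance(p, pos[e], cavity_center)
                 for p in pre_pos]
        crossing = sum(1 for d in dists if d <= SEAL_RADIUS)
        layer_counts.append(crossing)
        if crossing == 0:
            unsealed += 1
    return unsealed == 0, unsealed, int(np.median(layer_counts))


def diagnose(embryo: Embryo, graph=None) -> tuple[Outcome, EndpointDiagnostics]:
    """Classify an endpoint snapshot, returning the outcome and the
    geometric diagnostics.  Deterministic; invariant under rigid motions of
    the coordinates (up to grid rasterization)."""
    if embryo.n == 0:
        raise EmptyEmbryoError("cannot classify an empty embryo")
    counts, fractions = biological_counts(embryo)
    if graph is None:
        graph = rule_neighbor_graph(embryo)
    deep = deep_pre_indices(embryo, graph=graph)
    diag = EndpointDiagnostics(misplaced_pre_in_epi=len(deep))

    def outcome(cat):
        return Outcome(category=cat, counts=counts, fractions=fractions,
                       apoptosis_count=embryo.apoptosis_count,
                       deep_pre_at_endpoint=len(deep)), diag

    pos = embryo.positions
    lin = embryo.lineages
    te_mask = lin == int(Lineage.TE)
    icm_mask = ~te_mask

    if counts["TE"] == 0 or counts["ICM"] == 0:
        return outcome(OutcomeCategory.NO_TE)
    # composition defects take precedence (single-lineage ICM phenotypes)
    if counts["PRE"] == 0:
        return outcome(OutcomeCategory.EPI_ONLY)
    if counts["EPI"] + counts["UNDETERMINED_ICM"] == 0:
        return outcome(OutcomeCategory.PRE_ONLY)

    shell, cavity, one_sided, cavity_center = _shell_and_cavity(
        pos, te_mask, icm_mask)
    diag.te_shell_intact = shell
    diag.cavity_present = cavity
    diag.icm_one_sided = one_sided
    diag.cavity_center = cavity_center
    if not (shell and cavity and one_sided):
        return outcome(OutcomeCategory.NO_TE)

    if deep:
        return outcome(OutcomeCategory.PRE_IN_EPI_ERROR)

    sealed, unsealed, layer = _seal_test(pos, lin, cavity_center)
    diag.pre_layer_seals_epi = sealed
    diag.misplaced_epi_in_pre = unsealed
    diag.pre_layer_count = layer
    if not sealed:
        return outcome(OutcomeCategory.EPI_IN_PRE_ERROR)
    return outcome(OutcomeCategory.SUCCESS)


def classify(embryo: Embryo, graph=None) -> Outcome:
    """Classify an endpoint snapshot into success or one of the five errors."""
    return diagnose(embryo, graph=graph)[0]


def ensemble_stats(outcomes) -> dict:
    """Per-category fractions and moments of the composition statistics."""
    outcomes = [o for o in outcomes if o is not None]
    if not outcomes:
        raise ValueError("need at least one outcome")
    n = len(outcomes)
    stats: dict = {"n": n}
    for cat in OutcomeCategory:
        stats[f"frac_{cat.value}"] = (
            sum(1 for o in outcomes if o.category == cat) / n)

    def moments(key, vals):
        arr = np.array(vals, dtype=float)
        stats[f"mean_{key}"] = float(arr.mean())
        stats[f"sd_{key}"] = float(arr.std(ddof=1)) if n > 1 else 0.0

    moments("total_cells", [o.counts["total"] for o in outcomes])
    moments("icm_total", [o.fractions["icm_total"] for o in outcomes])
    moments("epi_icm", [o.fractions["epi_icm"] for o in outcomes])
    moments("pre_icm", [o.fractions["pre_icm"] for o in outcomes])
    moments("apoptosis", [o.apoptosis_count for o in outcomes])
    stats["frac_deep_pre_before_apoptosis"] = (
        sum(1 for o in outcomes if o.deep_pre_before_apoptosis) / n)
    stats["frac_deep_pre_at_endpoint"] = (
        sum(1 for o in outcomes if o.deep_pre_at_endpoint > 0) / n)
    return stats


def scale_2d_to_3d(n_2d: float, kind: str = "bulk") -> float:
    """Convert a 2D cell count to its 3D equivalent.

    Surface (TE) cells lie on a circle vs a sphere: N2D = sqrt(pi N3D);
    bulk (EPI/PrE/ICM) cells fill a disc vs a ball: N2D = (3/4 N3D sqrt(pi))^(2/3).
    """
    if n_2d < 0:
        raise ValueError("counts must be nonnegative")
    if kind == "te":
        return n_2d ** 2 / math.pi
    return (4.0 / 3.0) * n_2d ** 1.5 / math.sqrt(math.pi)


def scale_3d_to_2d(n_3d: float, kind: str = "bulk") -> float:
    """Inverse of :func:`scale_2d_to_3d`."""
    if n_3d < 0:
        raise ValueError("counts must be nonnegative")
    if kind == "te":
        return math.sqrt(math.pi * n_3d)
    return (0.75 * n_3d * math.sqrt(math.pi)) ** (2.0 / 3.0)
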