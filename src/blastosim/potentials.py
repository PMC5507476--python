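"""Pairwise interaction energies and forces.

The pair potential is

    V(d) = exp(-d) - S exp(-d / beta)

with center-to-center distance ``d`` in cell radii.  ``S`` encodes adhesion:
0.6 between ordinary cells, 0.4 for any pair involving a primitive-endoderm
cell once differential adhesion is active, and for TE-TE pairs the
polarity-dependent factor

    S = -1.4 (e1 x r12) . (e2 x r21)

which is maximal (+1.4) when the two polarities are parallel and
perpendicular to the separation (the tight-junction sheet configuration) and
negative for antiparallel polarities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import ModelParams
from .state import Embryo, Lineage

__all__ = [
    "pair_potential",
    "equilibrium_distance",
    "polar_attraction_factor",
    "effective_S",
    "total_force",
    "total_energy",
    "PairInteraction",
    "OverlapError",
]

_DUMMY_ADJ = np.zeros((1, 1), dtype=np.uint8)


class OverlapError(ValueError):
    """Two cells are (numerically) coincident."""


@dataclass
class PairInteraction:
    d: float
    S_eff: float
    V: float
    force_on_i: np.ndarray
    in_range: bool


def pair_potential(d: float, S: float, beta: float = 5.0) -> float:
    """Evaluate V(d) = exp(-d) - S exp(-d/beta) for a single pair."""
    if d <= 0:
        raise OverlapError(f"distance must be positive, got {d}")
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    return math.exp(-d) - S * math.exp(-d / beta)


def equilibrium_distance(S: float, beta: float = 5.0) -> float:
    """Distance at which the pair force vanishes: d* = -ln(S/beta)/(1 - 1/beta)."""
    if S <= 0:
        raise ValueError("pure repulsion has no finite equilibrium")
    return -math.log(S / beta) / (1.0 - 1.0 / beta)


def polar_attraction_factor(e1, e2, r12, prefactor: float = 1.4) -> float:
    """Polarity-dependent attraction factor for a TE-TE pair.

    ``S = -prefactor * (e1 x r12) . (e2 x r21)`` with ``r21 = -r12``; in 2D
    the cross products are the scalar z-components.  All three inputs must be
    unit vectors.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    r12 = np.asarray(r12, dtype=float)
    for name, v in (("e1", e1), ("e2", e2), ("r12", r12)):
        if not math.isclose(float(np.linalg.norm(v)), 1.0, abs_tol=1e-8):
            raise ValueError(f"{name} must be a unit vector")
    r21 = -r12
    if e1.shape[-1] == 2:
        c1 = e1[0] * r12[1] - e1[1] * r12[0]
        c2 = e2[0] * r21[1] - e2[1] * r21[0]
        return -prefactor * c1 * c2
    return -prefactor * float(np.dot(np.cross(e1, r12), np.cross(e2, r21)))


def effective_S(embryo: Embryo, i: int, j: int) -> PairInteraction:
    """Effective attraction factor, range flag, energy and force for a pair.

    TE-TE pairs use the polar factor and the short TE-TE cutoff; TE-ICM pairs
    use the 5-radius range; ICM-ICM pairs use the 5-radius truncation unless
    ``icm_global_potential`` is set.  After Rule 3, any pair involving a PrE
    cell is reduced to ``S_pre``; in the neutralized (DeltaRule-3) mode every
    pair involving an ICM cell uses ``S_neutral_adhesion``.
    """
    p = embryo.params
    ri = embryo.pos[i]
    rj = embryo.pos[j]
    diff = rj - ri
    d = float(np.linalg.norm(diff))
    if d <= 1e-9:
        raise OverlapError(f"cells {i} and {j} coincide")
    li = Lineage(int(embryo.lin[i]))
    lj = Lineage(int(embryo.lin[j]))
    neutral = embryo.rule3_active and getattr(embryo, "rule3_neutralized", False)
    if li == Lineage.TE and lj == Lineage.TE:
        u = diff / d
        s_eff = polar_attraction_factor(embryo.pol[i], embryo.pol[j], u,
                                        p.polar_prefactor)
        in_range = d < p.te_te_cutoff
    else:
        if neutral:
            s_eff = p.S_neutral_adhesion
        elif embryo.rule3_active and Lineage.PRE in (li, lj):
            s_eff = p.S_pre
        else:
            s_eff = p.S_default
        if li == Lineage.TE or lj == Lineage.TE:
            in_range = d <= p.te_icm_cutoff
        elif p.icm_global_potential:
            in_range = True
        else:
            in_range = d <= p.global_cutoff
    v = pair_potential(d, s_eff, p.beta) if in_range else 0.0
    f = _pair_force(embryo, i, j) if in_range else np.zeros(embryo.dim)
    return PairInteraction(d=d, S_eff=s_eff, V=v, force_on_i=f, in_range=in_range)


def _pair_force(embryo: Embryo, i: int, j: int) -> np.ndarray:
    forces = np.zeros((2, embryo.dim))
    torque = np.zeros(2)
    idx = np.array([i, j])
    _kernels.pair_accumulate(
        np.ascontiguousarray(embryo.pos[idx]), np.ascontiguousarray(embryo.lin[idx]),
        np.ascontiguousarray(embryo.pol[idx]), 2, embryo.dim,
        *_flags(embryo), False, _DUMMY_ADJ, forces, torque)
    return forces[0]


def _flags(embryo: Embryo):
    """Kernel argument tuple: (..., icm_global, rule3, neutral, tangential,
    filter_all); energy kernels drop the ``tangential`` entry."""
    p = embryo.params
    neutral = embryo.rule3_active and getattr(embryo, "rule3_neutralized", False)
    # the uncut ICM-ICM potential models protrusions of *specified* ICM
    # cells; the pre-polarity morula interacts with nearest neighbors only
    icm_global = p.icm_interaction == "global" and embryo.rule1_done
    if embryo.rule1_done:
        filter_all = (p.nearest_neighbor_interactions
                      and p.icm_interaction == "nearest")
    else:
        filter_all = (p.nearest_neighbor_interactions
                      and p.morula_interaction == "nearest")
    return (p.S_default, p.S_pre, p.S_neutral_adhesion, p.beta,
            p.polar_prefactor, p.te_te_cutoff, p.global_cutoff,
            icm_global, embryo.rule3_active and not neutral,
            neutral, p.polar_tangential_force, filter_all, p.te_icm_filtered)


def total_force(embryo: Embryo, te_adj: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Force on every cell (and the 2D polarity torques).

    Returns ``(forces, torques)``; forces are the exact negative gradient of
    the total pair energy, including the tangential component of the TE-TE
    polar term.  Raises :class:`OverlapError` on coincident cells.
    """
    n = embryo.n
    forces = np.zeros((n, embryo.dim))
    torques = np.zeros(n)
    if n < 2:
        return forces, torques
    use_adj, adj = _te_adjacency(embryo, te_adj)
    status = _kernels.pair_accumulate(
        embryo.positions.copy(), embryo.lineages.copy(),
        embryo.polarities.copy(), n, embryo.dim, *_flags(embryo),
        use_adj, adj, forces, torques)
    if status == _kernels.STATUS_OVERLAP:
        raise OverlapError("coincident cells in force evaluation")
    return forces, torques


def _te_adjacency(embryo: Embryo, te_adj=None):
    """Resolve the nearest-neighbor mask for force/energy evaluation."""
    if te_adj is not None:
        return True, te_adj
    if not embryo.params.nearest_neighbor_interactions:
        return False, _DUMMY_ADJ
    n = embryo.n
    adj = np.zeros((n, n), dtype=np.uint8)
    filter_all = _flags(embryo)[-1]
    _kernels.build_nn_adj(np.ascontiguousarray(embryo.positions),
                          np.ascontiguousarray(embryo.lineages), n,
                          embryo.dim, embryo.params.global_cutoff,
                          filter_all, adj)
    return True, adj


def total_energy(embryo: Embryo, te_adj: np.ndarray | None = None) -> float:
    """Total pair energy with the same range rules as :func:`total_force`."""
    use_adj, adj = _te_adjacency(embryo, te_adj)
    f = _flags(embryo)
    return float(_kernels.total_energy(
        embryo.positions.copy(), embryo.lineages.copy(),
        embryo.polarities.copy(), embryo.n, embryo.dim,
        *f[:10], f[11], f[12], use_adj, adj))
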