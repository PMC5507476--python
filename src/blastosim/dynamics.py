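"""Overdamped Euler integration of positions and TE polarity angles.

The equations of motion are inertia-free: dx/dt = -dV/dx + eta with additive
Gaussian noise per step, and for TE polarities dalpha/dt = -0.1 dV_p/dalpha
+ eta_p with the alignment potential V_p = -cos(alpha_i - alpha_j) summed
over in-range TE pairs.  Between discrete events (divisions, fate changes,
apoptosis) the system is relaxed until the deterministic displacement per
step falls below a tolerance, emulating the quasi-equilibrium growth of the
real embryo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .potentials import OverlapError, _flags, _DUMMY_ADJ
from .state import Embryo

__all__ = ["IntegratorState", "step_positions", "step_polarities", "relax",
           "NumericalInstabilityError"]


class NumericalInstabilityError(RuntimeError):
    """Non-finite forces encountered; carries a diagnostic snapshot."""

    def __init__(self, msg: str, snapshot=None):
        super().__init__(msg)
        self.snapshot = snapshot


@dataclass
class IntegratorState:
    """Step size, noise levels, and the seed stream for the integrator."""

    dt: float = 0.1
    noise_sd_position: float = 1e-3
    noise_sd_angle: float = np.pi * 1e-3
    polarity_mobility: float = 0.1
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rng is None:
            self.rng = np.random.default_rng(0)

    @classmethod
    def from_params(cls, params, rng=None) -> "IntegratorState":
        return cls(dt=params.dt, noise_sd_position=params.noise_sd_position,
                   noise_sd_angle=params.noise_sd_angle,
                   polarity_mobility=params.polarity_mobility, rng=rng)

    def kernel_seed(self) -> int:
        return int(self.rng.integers(0, 2**31 - 1))


def _run_kernel(embryo: Embryo, integrator: IntegratorState, max_steps: int,
                tol: float, noise_pos: float, noise_ang: float,
                te_adj=None) -> tuple[int, float]:
    n = embryo.n
    if n == 0:
        return 0, 0.0
    p = embryo.params
    pos = np.ascontiguousarray(embryo.positions)
    pol = np.ascontiguousarray(embryo.polarities)
    lin = np.ascontiguousarray(embryo.lineages)
    rebuild = 0
    if te_adj is not None:
        use_adj = True
        adj = te_adj
    elif p.nearest_neighbor_interactions:
        use_adj = True
        adj = np.zeros((n, n), dtype=np.uint8)
        rebuild = max(1, int(p.te_adj_rebuild_steps))
    else:
        use_adj = False
        adj = _DUMMY_ADJ
    steps, max_disp, status = _kernels.relax_kernel(
        pos, lin, pol, n, embryo.dim, *_flags(embryo), use_adj, adj, rebuild,
        integrator.dt, integrator.polarity_mobility, max_steps, tol,
        noise_pos, noise_ang, integrator.kernel_seed())
    embryo.pos[:n] = pos
    embryo.pol[:n] = pol
    if status == _kernels.STATUS_NONFINITE:
        raise NumericalInstabilityError(
            "non-finite forces during integration", snapshot=pos.copy())
    if status == _kernels.STATUS_OVERLAP:
        raise OverlapError("coincident cells during integration")
    return steps, max_disp


def step_positions(embryo: Embryo, integrator: IntegratorState,
                   n_steps: int = 1) -> Embryo:
    """Advance positions (and polarities) by ``n_steps`` Euler steps."""
    _run_kernel(embryo, integrator, n_steps, tol=-1.0,
                noise_pos=integrator.noise_sd_position,
                noise_ang=integrator.noise_sd_angle)
    return embryo

# positions and polarities are advanced together by the kernel (polarity
# update applied after the position update within each step); this alias
# exists for symmetry with the two damped equations of motion.
step_polarities = step_positions


def relax(embryo: Embryo, n_steps: int | None = None,
          integrator: IntegratorState | None = None, tol: float | None = None,
          noise: bool = True, te_adj=None) -> tuple[int, float]:
    """Relax the embryo toward mechanical equilibrium between events.

    Runs up to ``n_steps`` integration steps (default ``params.relax_steps``)
    and stops early once the largest deterministic per-step displacement
    ``dt * |F|`` drops below ``tol`` (default ``params.relax_tol``).  Returns
    ``(steps_used, final_max_displacement)`` as a convergence diagnostic.
    """
    p = embryo.params
    if integrator is None:
        integrator = IntegratorState.from_params(p, rng=embryo.rng)
    if n_steps is None:
        n_steps = p.relax_steps
    if n_steps == 0:
        return 0, 0.0
    if tol is None:
        tol = p.relax_tol
    return _run_kernel(
        embryo, integrator, n_steps, tol,
        noise_pos=integrator.noise_sd_position if noise else 0.0,
        noise_ang=integrator.noise_sd_angle if noise else 0.0,
        te_adj=te_adj)
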