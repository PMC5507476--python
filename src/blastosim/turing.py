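"""Lateral-inhibition lattice model of EPI/PrE proportioning.

The FGF4 fate rule alone, run on a fixed periodic grid of ICM cells
("an infinitely large ICM"), is a discrete Turing-like mechanism: local
amplification through the Nanog/Gata6 positive feedback, global inhibition
through FGF4 secretion by Nanog-high neighbors.  Asynchronous single-site
updates convert a site to PrE with probability equal to the high-FGF4
fraction of its neighborhood, and the PrE/ICM ratio converges to 1/2
independent of lattice size.
"""

from __future__ import annotations

import numpy as np

from .state import Lineage

__all__ = ["TuringLattice", "lattice_step", "lattice_ratio_trace"]


class TuringLattice:
    """Periodic 2D grid of fate states updated by the FGF4 rule.

    ``neighborhood`` is 8 (Moore, default) or 4 (von Neumann).
    """

    def __init__(self, width: int = 10, height: int | None = None,
                 neighborhood: int = 8, undetermined_weight: float = 1.0,
                 rng: np.random.Generator | int | None = None):
        if neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        self.width = int(width)
        self.height = int(height if height is not None else width)
        if self.width < 2 or self.height < 2:
            raise ValueError("lattice must be at least 2x2")
        self.neighborhood = neighborhood
        self.undetermined_weight = undetermined_weight
        self.rng = (rng if isinstance(rng, np.random.Generator)
                    else np.random.default_rng(rng))
        self.states = np.full((self.height, self.width),
                              int(Lineage.UNDETERMINED_ICM), dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    def neighbor_states(self, row: int, col: int) -> np.ndarray:
        if self.neighborhood == 8:
            offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                    (0, 1), (1, -1), (1, 0), (1, 1)]
        else:
            offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        return np.array([self.states[(row + dr) % self.height,
                                     (col + dc) % self.width]
                         for dr, dc in offs], dtype=np.int8)

    def pre_probability(self, row: int, col: int) -> float:
        """P(PrE) = weighted high-FGF4 neighbors / total neighbors."""
        nb = self.neighbor_states(row, col)
        high = ((nb == int(Lineage.EPI)).sum()
                + self.undetermined_weight
                * (nb == int(Lineage.UNDETERMINED_ICM)).sum())
        return float(high) / len(nb)

    def pre_icm_ratio(self) -> float:
        return float((self.states == int(Lineage.PRE)).mean())


def lattice_step(lattice: TuringLattice) -> TuringLattice:
    """Asynchronous update: one random site re-draws its fate."""
    rng = lattice.rng
    row = int(rng.integers(lattice.height))
    col = int(rng.integers(lattice.width))
    p = lattice.pre_probability(row, col)
    lattice.states[row, col] = int(
        Lineage.PRE if rng.random() < p else Lineage.EPI)
    return lattice


def lattice_ratio_trace(lattice: TuringLattice, n_updates: int) -> np.ndarray:
    """PrE/ICM ratio after each of ``n_updates`` asynchronous updates."""
    if n_updates < 1:
        raise ValueError("need at least one update")
    trace = np.empty(n_updates)
    n_pre = int((lattice.states == int(Lineage.PRE)).sum())
    n_sites = lattice.n_sites
    for k in range(n_updates):
        rng = lattice.rng
        row = int(rng.integers(lattice.height))
        col = int(rng.integers(lattice.width))
        old = lattice.states[row, col]
        p = lattice.pre_probability(row, col)
        new = int(Lineage.PRE if rng.random() < p else Lineage.EPI)
        lattice.states[row, col] = new
        if old != new:
            if new == int(Lineage.PRE):
                n_pre += 1
            elif old == int(Lineage.PRE):
                n_pre -= 1
        trace[k] = n_pre / n_sites
    return trace
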