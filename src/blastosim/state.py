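"""Domain types for cells, embryos, and simulation outcomes.

Cells are soft unit circles (2D) or unit spheres (3D); all distances are in
units of the cell radius.  A trophectoderm (TE) cell is physically represented
by *two* circles, reflecting that TE cells are about twice the size of inner
cell mass (ICM) cells, so "biological" TE counts are circle counts halved.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Lineage",
    "Cell",
    "Embryo",
    "Outcome",
    "OutcomeCategory",
    "EmptyEmbryoError",
    "biological_counts",
    "T_E30",
]

#: Absolute simulated time of the 16-cell stage (four cleavage rounds of
#: duration ln 2 each).  Stage markers E3.5/E4.0/E4.5 follow in steps of one
#: stage unit (``ModelParams.stage_unit``).
T_E30 = math.log(16.0)


class Lineage(enum.IntEnum):
    """Discrete cell fate; gene-expression levels are collapsed into states."""

    UNDETERMINED_ICM = 0  # coexpresses Nanog and Gata6, secretes FGF4
    TE = 1                # polarized trophectoderm
    EPI = 2               # Nanog-high epiblast, secretes FGF4
    PRE = 3               # Gata6-high primitive endoderm, weakly adhesive


#: Allowed fate transitions.  TE is terminal; EPI<->PRE switching is Rule 2;
#: PRE (and optionally EPI) removal is Rule 4 apoptosis.
ALLOWED_TRANSITIONS = {
    (Lineage.UNDETERMINED_ICM, Lineage.TE),
    (Lineage.UNDETERMINED_ICM, Lineage.EPI),
    (Lineage.UNDETERMINED_ICM, Lineage.PRE),
    (Lineage.EPI, Lineage.PRE),
    (Lineage.PRE, Lineage.EPI),
}


class EmptyEmbryoError(ValueError):
    """Raised when an operation requires at least one living cell."""


class OutcomeCategory(enum.Enum):
    SUCCESS = "success"
    NO_TE = "no_te"
    EPI_ONLY = "epi_only"
    PRE_ONLY = "pre_only"
    EPI_IN_PRE_ERROR = "epi_in_pre_error"
    PRE_IN_EPI_ERROR = "pre_in_epi_error"


@dataclass
class Cell:
    """A single simulated circle/sphere.

    ``polarity`` is a unit vector and is only meaningful for TE cells.
    ``te_pair_id`` links the two circles jointly representing one biological
    TE cell (daughters inherit the mother's pair id for lineage bookkeeping).
    """

    id: int
    position: np.ndarray
    lineage: Lineage
    polarity: np.ndarray | None = None
    alive: bool = True
    te_pair_id: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.lineage == Lineage.TE:
            if self.polarity is None:
                raise ValueError("TE cells require a polarity vector")
            p = np.asarray(self.polarity, dtype=float)
            n = np.linalg.norm(p)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError(f"TE polarity must be a unit vector, |p|={n}")
            self.polarity = p / n


class Embryo:
    """Collection of cells plus the simulation clock.

    Internally a structure of arrays for speed; :attr:`cells` materializes
    :class:`Cell` views for inspection.  Dead cells are dropped from the
    arrays (apoptosis is the only removal event and happens at the endpoint).
    """

    def __init__(self, params, dim: int = 2, rng: np.random.Generator | None = None):
        self.params = params
        self.dim = int(dim)
        self.rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
        n0 = 64
        self.pos = np.zeros((n0, self.dim))
        self.lin = np.zeros(n0, dtype=np.int8)
        self.pol = np.zeros((n0, self.dim))
        self.pair = np.full(n0, -1, dtype=np.int32)
        self.n = 0
        self.t = 0.0
        self.rule1_done = False
        self.rule3_active = False
        self.rule3_neutralized = False
        self.apoptosis_count = 0
        self._next_pair_id = 0

    # -- container plumbing -------------------------------------------------

    def _grow(self, need: int) -> None:
        cap = len(self.lin)
        if need <= cap:
            return
        new = max(need, 2 * cap)
        self.pos = np.resize(self.pos, (new, self.dim))
        self.pol = np.resize(self.pol, (new, self.dim))
        self.lin = np.resize(self.lin, new)
        self.pair = np.resize(self.pair, new)

    def add_cell(self, position, lineage: Lineage, polarity=None, pair_id: int = -1) -> int:
        self._grow(self.n + 1)
        i = self.n
        self.pos[i] = np.asarray(position, dtype=float)
        self.lin[i] = int(lineage)
        self.pol[i] = 0.0 if polarity is None else np.asarray(polarity, dtype=float)
        self.pair[i] = pair_id
        self.n += 1
        return i

    def remove_cells(self, idx) -> None:
        keep = np.ones(self.n, dtype=bool)
        keep[np.asarray(idx, dtype=int)] = False
        m = int(keep.sum())
        self.pos[:m] = self.pos[:self.n][keep]
        self.pol[:m] = self.pol[:self.n][keep]
        self.lin[:m] = self.lin[:self.n][keep]
        self.pair[:m] = self.pair[:self.n][keep]
        self.n = m

    def set_lineage(self, i: int, new: Lineage) -> None:
        old = Lineage(int(self.lin[i]))
        if old != new and (old, new) not in ALLOWED_TRANSITIONS:
            raise ValueError(f"forbidden lineage transition {old.name} -> {new.name}")
        self.lin[i] = int(new)

    @property
    def positions(self) -> np.ndarray:
        return self.pos[: self.n]

    @property
    def lineages(self) -> np.ndarray:
        return self.lin[: self.n]

    @property
    def polarities(self) -> np.ndarray:
        return self.pol[: self.n]

    @property
    def cells(self) -> list[Cell]:
        out = []
        for i in range(self.n):
            lin = Lineage(int(self.lin[i]))
            out.append(
                Cell(
                    id=i,
                    position=self.pos[i].copy(),
                    lineage=lin,
                    polarity=self.pol[i].copy() if lin == Lineage.TE else None,
                    te_pair_id=int(self.pair[i]) if self.pair[i] >= 0 else None,
                )
            )
        return out

    def copy(self) -> "Embryo":
        other = Embryo(self.params, dim=self.dim, rng=self.rng)
        other.pos = self.pos.copy()
        other.pol = self.pol.copy()
        other.lin = self.lin.copy()
        other.pair = self.pair.copy()
        other.n = self.n
        other.t = self.t
        other.rule1_done = self.rule1_done
        other.rule3_active = self.rule3_active
        other.rule3_neutralized = self.rule3_neutralized
        other.apoptosis_count = self.apoptosis_count
        other._next_pair_id = self._next_pair_id
        return other

    def new_pair_id(self) -> int:
        self._next_pair_id += 1
        return self._next_pair_id - 1

    # -- counts -------------------------------------------------------------

    def lineage_circle_counts(self) -> dict[Lineage, int]:
        lin = self.lineages
        return {lg: int((lin == int(lg)).sum()) for lg in Lineage}


@dataclass
class Outcome:
    """Classified endpoint of one replicate."""

    category: OutcomeCategory
    counts: dict = field(default_factory=dict)       # biological counts per lineage
    fractions: dict = field(default_factory=dict)    # icm_total, epi_icm, pre_icm
    apoptosis_count: int = 0
    deep_pre_before_apoptosis: bool = False
    deep_pre_at_endpoint: int = 0


def biological_counts(embryo: Embryo) -> tuple[dict, dict]:
    """Per-lineage biological counts and ICM fractions.

    Two TE circles represent one biological TE cell, so the biological TE
    count is the TE circle count halved (rounded half up).  Undetermined ICM
    cells remaining at the endpoint are Nanog-coexpressing and are counted
    with the epiblast in the EPI/ICM fraction.
    """
    if embryo.n == 0:
        raise EmptyEmbryoError("embryo has no living cells")
    c = embryo.lineage_circle_counts()
    te = math.floor(c[Lineage.TE] / 2.0 + 0.5)
    undet = c[Lineage.UNDETERMINED_ICM]
    epi = c[Lineage.EPI]
    pre = c[Lineage.PRE]
    icm = undet + epi + pre
    total = te + icm
    counts = {"TE": te, "UNDETERMINED_ICM": undet, "EPI": epi, "PRE": pre,
              "ICM": icm, "total": total}
    fractions = {
        "icm_total": icm / total if total else 0.0,
        "epi_icm": (epi + undet) / icm if icm else 0.0,
        "pre_icm": pre / icm if icm else 0.0,
    }
    return counts, fractions
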