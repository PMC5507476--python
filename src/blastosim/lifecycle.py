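"""The four developmental rules and cell division.

Rule 1  Develop polarity, if surface cell (16-cell stage): cells with fewer
        than 5 contact neighbors become TE, polarity pointing radially out;
        each TE cell becomes two unit circles.
Rule 2  Switch fate, if surrounded by too many cells of the same type: at
        division, mother and daughter convert to PrE with probability equal
        to the fraction of high-FGF4 (EPI or undetermined) cells among the
        ICM neighborhood, else to EPI.
Rule 3  Less adhesion, if PrE progenitor (E3.5): attraction factor for any
        pair involving a PrE cell drops from 0.6 to 0.4.
Rule 4  Die, if in a wrong position (E4.5): PrE cells surrounded by more
        than 3 non-PrE ICM cells undergo apoptosis.
"""

from __future__ import annotations

import numpy as np

from .neighbors import count_lineage_neighbors, rule_neighbor_graph
from .params import RuleConfig
from .state import Embryo, Lineage

__all__ = [
    "apply_rule1_polarity",
    "divide_cell",
    "select_divider",
    "rule2_pre_probability",
    "apply_rule2_fate",
    "apply_rule3_adhesion",
    "apply_rule4_apoptosis",
    "deep_pre_indices",
]


def surface_cells(embryo: Embryo, graph=None) -> list[int]:
    """Indices of surface cells at the polarity stage.

    Default criterion ("neighbors"): fewer than 5 nearest neighbors.  The
    alternative "exposure" criterion marks cells with a contact-free angular
    sector wider than ``rule1_exposure_angle`` (2D only) - the geometric
    reading of an apical, contact-free surface - which is robust to packing
    irregularities that can leave an inner-classified cell sitting on the
    hull.
    """
    if graph is None:
        graph = rule_neighbor_graph(embryo)
    p = embryo.params
    n0 = embryo.n
    if embryo.dim == 3:
        # outward exposure: no nearest neighbor within 60 degrees of the
        # outward radial direction (the 2D "< 5 neighbors" count does not
        # transfer to 3D, where interior cells have ~12 nearest neighbors)
        centroid = embryo.positions.mean(axis=0)
        out = []
        for i in range(n0):
            radial = embryo.pos[i] - centroid
            nr = np.linalg.norm(radial)
            if nr < 1e-9:
                continue
            radial = radial / nr
            exposed = True
            for j in graph.neighbors(i):
                v = embryo.pos[j] - embryo.pos[i]
                v = v / np.linalg.norm(v)
                if float(v @ radial) > 0.5:
                    exposed = False
                    break
            if exposed:
                out.append(i)
        return out
    if p.rule1_surface == "neighbors":
        return [i for i in range(n0) if graph.degree(i) <= 4]
    out = []
    for i in range(n0):
        nbrs = graph.neighbors(i)
        if len(nbrs) <= 1:
            out.append(i)
            continue
        vecs = embryo.positions[nbrs] - embryo.pos[i]
        ang = np.sort(np.arctan2(vecs[:, 1], vecs[:, 0]))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        if gaps.max() > p.rule1_exposure_angle:
            out.append(i)
    return out


def apply_rule1_polarity(embryo: Embryo, te_offset: float = 0.8) -> Embryo:
    """Assign TE fate and radial polarity to surface cells.

    Cells with 4 or fewer neighbors in the contact graph become TE with
    polarity pointing radially outward from the cell-mass centroid, and each
    is expanded to two unit circles placed symmetrically at +-``te_offset``
    along the local tangent (so the pair straddles the mother's position,
    close to the polar-pair equilibrium spacing of ~1.6, which perturbs the
    nascent shell as little as possible), sharing polarity and pair id.  The
    remaining inner cells become undetermined ICM.  The 2x TE proliferation
    is implicit: a biological TE cell is two circles, each dividing at the
    common per-circle rate.
    """
    if embryo.n < 2:
        raise ValueError("Rule 1 requires at least 2 cells")
    if embryo.rule1_done:
        raise ValueError("Rule 1 already applied")
    graph = rule_neighbor_graph(embryo)
    centroid = embryo.positions.mean(axis=0)
    n0 = embryo.n
    outer = surface_cells(embryo, graph)
    rng = embryo.rng
    for i in outer:
        radial = embryo.pos[i] - centroid
        norm = np.linalg.norm(radial)
        if norm < 1e-9:
            radial = rng.normal(size=embryo.dim)
            norm = np.linalg.norm(radial)
        polarity = radial / norm
        pair_id = embryo.new_pair_id()
        embryo.set_lineage(i, Lineage.TE)
        embryo.pol[i] = polarity
        embryo.pair[i] = pair_id
        # second circle of the biological TE cell, along the local tangent
        if embryo.dim == 2:
            tangent = np.array([-polarity[1], polarity[0]])
        else:
            trial = np.cross(polarity, rng.normal(size=3))
            tangent = trial / np.linalg.norm(trial)
        offset = te_offset * tangent + 0.02 * rng.normal(size=embryo.dim)
        embryo.add_cell(embryo.pos[i] + offset, Lineage.TE,
                        polarity=polarity, pair_id=pair_id)
        embryo.pos[i] -= offset
    embryo.rule1_done = True
    return embryo


def select_divider(embryo: Embryo, rng: np.random.Generator | None = None) -> int:
    """Pick the next dividing circle uniformly at random.

    Uniform selection over circles makes a biological TE cell (two circles)
    divide at twice the rate of an ICM cell, as reported for trophectoderm
    proliferation; before Rule 1 all cells are single circles, so selection
    is uniform over cells.
    """
    if embryo.n == 0:
        raise ValueError("no living cells")
    rng = embryo.rng if rng is None else rng
    return int(rng.integers(embryo.n))


def divide_cell(embryo: Embryo, i: int, jitter: float = 0.05) -> int:
    """Insert a daughter between cell ``i`` and its nearest neighbor.

    The daughter inherits the mother's lineage and, for TE, its polarity
    orientation and pair id.  A small random jitter breaks the exact
    midpoint degeneracy; the caller is expected to relax afterwards.
    Returns the daughter's index.
    """
    rng = embryo.rng
    mother_pos = embryo.pos[i].copy()
    if embryo.n == 1:
        direction = rng.normal(size=embryo.dim)
        direction /= np.linalg.norm(direction)
        new_pos = mother_pos + 2.0 * direction
    else:
        diff = embryo.positions - mother_pos
        d = np.linalg.norm(diff, axis=1)
        d[i] = np.inf
        if embryo.dim == 3:
            # center of the 3 nearest neighbors: close to the minimal-energy
            # position, which shortens relaxation in 3D
            k = min(3, embryo.n - 1)
            nn = np.argpartition(d, k - 1)[:k]
            new_pos = (embryo.positions[nn].sum(axis=0) + mother_pos) / (k + 1)
        else:
            nn = int(np.argmin(d))
            new_pos = 0.5 * (mother_pos + embryo.pos[nn])
        new_pos = new_pos + jitter * rng.normal(size=embryo.dim)
    lineage = Lineage(int(embryo.lin[i]))
    polarity = embryo.pol[i].copy() if lineage == Lineage.TE else None
    pair_id = int(embryo.pair[i])
    return embryo.add_cell(new_pos, lineage, polarity=polarity, pair_id=pair_id)


def rule2_pre_probability(embryo: Embryo, i: int, rule_config: RuleConfig,
                          graph=None, exclude: int | None = None) -> float:
    """P(PrE) for cell ``i``: weighted high-FGF4 fraction of its ICM neighbors.

    H = #EPI + w * #undetermined (w = ``fgf_undetermined_weight``), N = total
    ICM neighbors (plain count); TE neighbors do not participate.  With no
    ICM neighbors the cell adopts EPI (probability 0, documented convention).
    """
    if graph is None:
        graph = rule_neighbor_graph(embryo)
    w = rule_config.fgf_undetermined_weight
    n_epi = n_undet = n_icm = 0
    for j in graph.neighbors(i):
        if j == exclude:
            continue
        lg = Lineage(int(embryo.lin[j]))
        if lg == Lineage.EPI:
            n_epi += 1
            n_icm += 1
        elif lg == Lineage.UNDETERMINED_ICM:
            n_undet += 1
            n_icm += 1
        elif lg == Lineage.PRE:
            n_icm += 1
    if n_icm == 0:
        return 0.0
    return (n_epi + w * n_undet) / n_icm


def apply_rule2_fate(embryo: Embryo, mother: int, daughter: int,
                     rule_config: RuleConfig, graph=None) -> Embryo:
    """FGF4-mediated fate assignment of mother and daughter at division.

    Both draw independently from the mother's pre-division neighborhood
    (the just-inserted daughter is excluded from the count).  Modes:
    ``no_fgf`` always EPI, ``excess_fgf`` always PrE; ``delayed``/``off``
    gating is handled by the experiment schedule.
    """
    mode = rule_config.rule2_mode
    if mode == "no_fgf":
        p = 0.0
    elif mode == "excess_fgf":
        p = 1.0
    else:
        p = rule2_pre_probability(embryo, mother, rule_config, graph=graph,
                                  exclude=daughter)
    rng = embryo.rng
    for idx in (mother, daughter):
        new = Lineage.PRE if rng.random() < p else Lineage.EPI
        if Lineage(int(embryo.lin[idx])) != new:
            embryo.set_lineage(idx, new)
    return embryo


def apply_rule3_adhesion(embryo: Embryo, rule_config: RuleConfig) -> Embryo:
    """Activate differential adhesion (or its neutralized control)."""
    embryo.rule3_active = True
    embryo.rule3_neutralized = rule_config.rule3_mode == "neutralized"
    return embryo


def deep_pre_indices(embryo: Embryo, graph=None,
                     threshold: int | None = None) -> list[int]:
    """PrE cells buried in the EPI core: more than ``threshold`` non-PrE ICM
    neighbors (TE neighbors are not counted as 'precursors')."""
    if graph is None:
        graph = rule_neighbor_graph(embryo)
    if threshold is None:
        threshold = embryo.params.apoptosis_nonpre_neighbor_threshold
    out = []
    for i in range(embryo.n):
        if Lineage(int(embryo.lin[i])) != Lineage.PRE:
            continue
        if count_lineage_neighbors(graph, embryo, i, "non_pre_icm") > threshold:
            out.append(i)
    return out


def apply_rule4_apoptosis(embryo: Embryo, rule_config: RuleConfig,
                          graph=None) -> tuple[Embryo, int]:
    """Remove mispositioned PrE cells (and, in the variant, random EPI cells).

    Returns the embryo and the number of apoptotic cells.
    """
    doomed = deep_pre_indices(embryo, graph=graph)
    frac = rule_config.epi_apoptosis_fraction
    if frac > 0:
        epi = [i for i in range(embryo.n)
               if Lineage(int(embryo.lin[i])) == Lineage.EPI]
        k = int(round(frac * len(epi)))
        if k > 0:
            doomed = list(doomed) + list(
                embryo.rng.choice(epi, size=k, replace=False))
    doomed = sorted(set(int(i) for i in doomed))
    if doomed:
        embryo.remove_cells(doomed)
    embryo.apoptosis_count += len(doomed)
    return embryo, len(doomed)
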