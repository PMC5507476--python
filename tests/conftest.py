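import numpy as np
import pytest

from blastosim import Embryo, Lineage, ModelParams


def build_embryo(cells, params=None, dim=2, seed=0, rule1_done=True,
                 rule3_active=False):
    """Construct an embryo from (position, lineage[, polarity]) tuples."""
    params = params if params is not None else ModelParams()
    embryo = Embryo(params, dim=dim, rng=np.random.default_rng(seed))
    for spec in cells:
        pos, lineage = spec[0], spec[1]
        pol = spec[2] if len(spec) > 2 else None
        embryo.add_cell(np.asarray(pos, dtype=float), lineage, polarity=pol)
    embryo.rule1_done = rule1_done
    embryo.rule3_active = rule3_active
    return embryo


def te_ring_cells(n=50, radius=12.0):
    cells = []
    for k in range(n):
        th = 2 * np.pi * k / n
        pol = np.array([np.cos(th), np.sin(th)])
        cells.append((radius * pol, Lineage.TE, pol))
    return cells


def blastocyst_cells(n_te=50, radius=12.0):
    """A hand-built successful endpoint: closed TE ring, EPI core attached
    to the top wall, PrE arc sealing the EPI from the cavity below."""
    cells = te_ring_cells(n_te, radius)
    epi = [(-2.0, 10.2), (0.0, 10.3), (2.0, 10.2), (-1.0, 8.7), (1.0, 8.7)]
    pre = [(-2.7, 7.4), (-0.9, 6.8), (0.9, 6.8), (2.7, 7.4)]
    cells += [(np.array(p), Lineage.EPI) for p in epi]
    cells += [(np.array(p), Lineage.PRE) for p in pre]
    return cells


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def blastocyst(params):
    return build_embryo(blastocyst_cells(), params=params, rule3_active=True)
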