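import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blastosim import (Lineage, ModelParams, equilibrium_distance,
                       pair_potential, polar_attraction_factor, total_energy,
                       total_force)
from blastosim.potentials import OverlapError, effective_S
from conftest import build_embryo, te_ring_cells


class TestPairPotential:
    def test_reference_value(self):
        # V(2) = exp(-2) - 0.6 exp(-0.4)
        assert pair_potential(2.0, 0.6, 5.0) == pytest.approx(-0.2668567, abs=1e-6)

    def test_pure_repulsion_when_attraction_off(self):
        for d in (0.5, 1.0, 3.0, 4.9):
            assert pair_potential(d, 0.0) == pytest.approx(math.exp(-d))
            assert pair_potential(d, 0.0) > 0

    def test_equilibrium_distance_closed_form(self):
        d_star = equilibrium_distance(0.6, 5.0)
        assert d_star == pytest.approx(2.650331, abs=1e-5)
        # force changes sign across d*
        h = 1e-6
        slope = (pair_potential(d_star + h, 0.6) - pair_potential(d_star - h, 0.6)) / (2 * h)
        assert abs(slope) < 1e-6

    def test_overlap_rejected(self):
        with pytest.raises(OverlapError):
            pair_potential(0.0, 0.6)
        with pytest.raises(OverlapError):
            pair_potential(-1.0, 0.6)

    @given(d=st.floats(0.2, 4.9), s=st.floats(0.05, 0.95))
    @settings(max_examples=40, deadline=None)
    def test_repulsive_below_attractive_above_equilibrium(self, d, s):
        d_star = equilibrium_distance(s, 5.0)
        h = 1e-5
        slope = (pair_potential(d + h, s) - pair_potential(d - h, s)) / (2 * h)
        if d < d_star - 1e-3:
            assert slope < 0  # inward-decreasing V: repulsion
        elif d > d_star + 1e-3:
            assert slope > 0


class TestPolarFactor:
    def test_parallel_perpendicular_is_maximal(self):
        s = polar_attraction_factor((0, 1), (0, 1), (1, 0))
        assert s == pytest.approx(1.4)

    def test_antiparallel_is_maximally_repulsive(self):
        s = polar_attraction_factor((0, 1), (0, -1), (1, 0))
        assert s == pytest.approx(-1.4)

    def test_polarity_along_separation_vanishes(self):
        assert polar_attraction_factor((1, 0), (0, 1), (1, 0)) == pytest.approx(0.0)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            polar_attraction_factor((0, 2), (0, 1), (1, 0))

    @given(a=st.floats(0, 2 * math.pi), b=st.floats(0, 2 * math.pi),
           c=st.floats(0, 2 * math.pi))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_matches_dot_identity(self, a, b, c):
        e1 = np.array([math.cos(a), math.sin(a)])
        e2 = np.array([math.cos(b), math.sin(b)])
        u = np.array([math.cos(c), math.sin(c)])
        s = polar_attraction_factor(e1, e2, u)
        assert abs(s) <= 1.4 + 1e-9
        ident = 1.4 * (e1 @ e2 - (e1 @ u) * (e2 @ u))
        assert s == pytest.approx(ident, abs=1e-9)

    def test_3d_form_agrees_with_cross_products(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            e1, e2, u = (v / np.linalg.norm(v) for v in rng.normal(size=(3, 3)))
            s = polar_attraction_factor(e1, e2, u)
            ident = 1.4 * (e1 @ e2 - (e1 @ u) * (e2 @ u))
            assert s == pytest.approx(ident, abs=1e-9)


class TestEffectiveS:
    def _pair(self, l1, l2, d=3.0, rule3=False, neutral=False):
        cells = [((0.0, 0.0), l1), ((d, 0.0), l2)]
        cells = [(p, lg, np.array([0.0, 1.0]) if lg == Lineage.TE else None)
                 for p, lg in cells]
        e = build_embryo(cells, rule3_active=rule3)
        e.rule3_neutralized = neutral
        return effective_S(e, 0, 1)

    def test_pre_pairs_weaken_after_differential_adhesion(self):
        assert self._pair(Lineage.PRE, Lineage.EPI, rule3=True).S_eff == 0.4
        assert self._pair(Lineage.PRE, Lineage.TE, rule3=True).S_eff == 0.4
        assert self._pair(Lineage.EPI, Lineage.EPI, rule3=True).S_eff == 0.6

    def test_before_trigger_all_pairs_default(self):
        assert self._pair(Lineage.PRE, Lineage.PRE, rule3=False).S_eff == 0.6

    def test_neutralized_mode_flattens_icm_adhesion(self):
        pi = self._pair(Lineage.EPI, Lineage.PRE, rule3=True, neutral=True)
        assert pi.S_eff == 0.5

    def test_te_te_uses_polar_factor_and_short_range(self):
        pi = self._pair(Lineage.TE, Lineage.TE, d=2.0)
        assert pi.S_eff == pytest.approx(1.4)
        assert pi.in_range
        assert not self._pair(Lineage.TE, Lineage.TE, d=3.0).in_range


class TestTotalForce:
    def test_pair_at_equilibrium_has_no_net_force(self):
        d_star = equilibrium_distance(0.6, 5.0)
        e = build_embryo([((0, 0), Lineage.EPI), ((d_star, 0), Lineage.EPI)])
        f, _ = total_force(e)
        assert np.abs(f).max() < 1e-9

    def test_close_pair_repels(self):
        e = build_embryo([((0, 0), Lineage.EPI), ((1.5, 0), Lineage.EPI)])
        f, _ = total_force(e)
        assert f[0, 0] < 0 < f[1, 0]

    def test_isolated_cell_feels_nothing(self):
        e = build_embryo([((0, 0), Lineage.EPI)])
        f, _ = total_force(e)
        assert np.all(f == 0)

    def test_antisymmetry_to_machine_precision(self):
        rng = np.random.default_rng(7)
        cells = []
        for k in range(12):
            pol = rng.normal(size=2)
            pol /= np.linalg.norm(pol)
            lg = [Lineage.TE, Lineage.EPI, Lineage.PRE][k % 3]
            cells.append((rng.uniform(-4, 4, 2), lg,
                          pol if lg == Lineage.TE else None))
        e = build_embryo(cells, rule3_active=True)
        f, _ = total_force(e)
        assert np.abs(f.sum(axis=0)).max() < 1e-11

    def test_overlapping_cells_raise(self):
        e = build_embryo([((0, 0), Lineage.EPI), ((0, 0), Lineage.EPI)])
        with pytest.raises(OverlapError):
            total_force(e)

    def test_matches_numerical_gradient_of_energy(self):
        # analytic force vs central differences, including the tangential
        # component of the polar TE-TE term, on 100 random pairs
        rng = np.random.default_rng(11)
        params = ModelParams(nearest_neighbor_interactions=False)
        for _ in range(100):
            both_te = rng.random() < 0.5
            if both_te:
                lineages = (Lineage.TE, Lineage.TE)
                d = rng.uniform(0.8, 2.4)
            else:
                lineages = (Lineage.EPI, rng.choice([Lineage.PRE, Lineage.EPI,
                                                     Lineage.UNDETERMINED_ICM]))
                d = rng.uniform(0.8, 4.8)
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            cells = []
            for k, lg in enumerate(lineages):
                pol = rng.normal(size=2)
                pol /= np.linalg.norm(pol)
                cells.append((d * direction * k, lg,
                              pol if lg == Lineage.TE else None))
            e = build_embryo(cells, params=params, rule3_active=True)
            f, _ = total_force(e)
            h = 1e-5
            for i in range(2):
                for m in range(2):
                    e.pos[i, m] += h
                    ep = total_energy(e)
                    e.pos[i, m] -= 2 * h
                    em = total_energy(e)
                    e.pos[i, m] += h
                    assert f[i, m] == pytest.approx(-(ep - em) / (2 * h), abs=1e-6)


def test_te_ring_energy_prefers_outward_winding(params):
    # sanity: a radial-polarity ring is strongly bound (negative energy)
    e = build_embryo(te_ring_cells(16, radius=16 * 1.6 / (2 * np.pi)),
                     params=params)
    assert total_energy(e) < -5.0
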