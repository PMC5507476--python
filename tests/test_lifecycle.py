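import numpy as np
import pytest

from blastosim import (Lineage, ModelParams, NeighborGraph, RuleConfig,
                       apply_rule1_polarity, apply_rule2_fate,
                       apply_rule3_adhesion, apply_rule4_apoptosis,
                       deep_pre_indices, divide_cell, select_divider)
from blastosim.lifecycle import rule2_pre_probability, surface_cells
from conftest import build_embryo


def compact_16_cluster(seed=42):
    """Grow a 16-cell morula the way the simulator does."""
    from blastosim.dynamics import IntegratorState
    from blastosim.experiments import _grow_rounds_to
    from blastosim.state import Embryo

    params = ModelParams()
    rng = np.random.default_rng(seed)
    e = Embryo(params, dim=2, rng=rng)
    e.add_cell(np.zeros(2), Lineage.UNDETERMINED_ICM)
    _grow_rounds_to(e, 16, IntegratorState.from_params(params, rng=rng))
    return e


class TestRule1:
    def test_16_cell_split_outer_te_inner_icm(self):
        e = compact_16_cluster()
        outer = set(surface_cells(e))
        centroid = e.positions.mean(axis=0)
        r = np.linalg.norm(e.positions - centroid, axis=1)
        # surface cells are farther out than inner cells on average
        assert len(outer) in range(6, 15)
        inner = [i for i in range(16) if i not in outer]
        assert np.mean(r[list(outer)]) > np.mean(r[inner])
        apply_rule1_polarity(e)
        assert (e.lineages == int(Lineage.TE)).sum() == 2 * len(outer)
        # polarity points radially outward and both pair circles share it
        for i in range(e.n):
            if e.lin[i] == int(Lineage.TE):
                radial = e.pos[i] - centroid
                assert e.pol[i] @ radial > 0
        pair_ids = e.pair[:e.n][e.lineages == int(Lineage.TE)]
        _, counts = np.unique(pair_ids, return_counts=True)
        assert np.all(counts == 2)

    def test_small_mutually_close_cluster_all_te(self):
        cells = [((np.cos(2 * np.pi * k / 5), np.sin(2 * np.pi * k / 5)),
                  Lineage.UNDETERMINED_ICM) for k in range(5)]
        e = build_embryo(cells, rule1_done=False)
        apply_rule1_polarity(e)
        assert np.all(e.lineages == int(Lineage.TE))

    def test_cannot_fire_twice(self):
        e = compact_16_cluster()
        apply_rule1_polarity(e)
        with pytest.raises(ValueError):
            apply_rule1_polarity(e)

    def test_needs_two_cells(self):
        e = build_embryo([((0, 0), Lineage.UNDETERMINED_ICM)], rule1_done=False)
        with pytest.raises(ValueError):
            apply_rule1_polarity(e)


class TestDivision:
    def test_daughter_at_midpoint(self):
        e = build_embryo([((0, 0), Lineage.EPI), ((2, 0), Lineage.EPI)])
        j = divide_cell(e, 0, jitter=0.0)
        assert np.allclose(e.pos[j], [1, 0])

    def test_te_daughter_inherits_fate_and_polarity(self):
        pol = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])
        e = build_embryo([((0, 0), Lineage.TE, pol), ((1.6, 0), Lineage.TE, pol)])
        j = divide_cell(e, 0)
        assert Lineage(int(e.lin[j])) == Lineage.TE
        assert np.allclose(e.pol[j], pol)

    def test_single_cell_divides_to_two(self):
        e = build_embryo([((0, 0), Lineage.UNDETERMINED_ICM)], rule1_done=False)
        divide_cell(e, 0)
        assert e.n == 2
        assert np.linalg.norm(e.pos[1] - e.pos[0]) > 0.5

    def test_selection_uniform_over_circles_gives_te_twice_the_rate(self):
        # 8 biological TE cells (16 circles) + 8 ICM -> P(TE divides) = 2/3
        cells = [((2.0 * k, 0.0), Lineage.TE, (0.0, 1.0)) for k in range(16)]
        cells += [((2.0 * k, 5.0), Lineage.EPI) for k in range(8)]
        e = build_embryo(cells, seed=77)
        draws = 6000
        te_hits = sum(int(e.lin[select_divider(e)]) == int(Lineage.TE)
                      for _ in range(draws))
        p = te_hits / draws
        assert abs(p - 2 / 3) < 0.025  # ~4 binomial sd


class TestRule2:
    def _embryo_with_neighbors(self, lineages):
        cells = [((0.0, 0.0), Lineage.UNDETERMINED_ICM)]
        for k, lg in enumerate(lineages):
            th = 2 * np.pi * k / max(len(lineages), 1)
            pol = (np.cos(th), np.sin(th)) if lg == Lineage.TE else None
            cells.append(((2.2 * np.cos(th), 2.2 * np.sin(th)), lg, pol))
        e = build_embryo(cells)
        g = NeighborGraph(adjacency={0: list(range(1, len(cells)))})
        return e, g

    def test_probability_is_high_fgf_fraction(self):
        e, g = self._embryo_with_neighbors(
            [Lineage.EPI, Lineage.EPI, Lineage.EPI, Lineage.PRE])
        p = rule2_pre_probability(e, 0, RuleConfig(), graph=g)
        assert p == pytest.approx(3 / 4)

    def test_all_pre_neighbors_force_epi(self):
        e, g = self._embryo_with_neighbors([Lineage.PRE] * 4)
        assert rule2_pre_probability(e, 0, RuleConfig(), graph=g) == 0.0

    def test_no_icm_neighbors_defaults_to_epi(self):
        e, g = self._embryo_with_neighbors([Lineage.TE, Lineage.TE])
        assert rule2_pre_probability(e, 0, RuleConfig(), graph=g) == 0.0

    def test_undetermined_weight_halves_contribution(self):
        e, g = self._embryo_with_neighbors(
            [Lineage.UNDETERMINED_ICM, Lineage.UNDETERMINED_ICM, Lineage.PRE,
             Lineage.PRE])
        rc = RuleConfig(fgf_undetermined_weight=0.5)
        assert rule2_pre_probability(e, 0, rc, graph=g) == pytest.approx(0.25)

    def test_matches_brute_force_counting_on_random_neighborhoods(self):
        rng = np.random.default_rng(13)
        rc = RuleConfig()
        for _ in range(1000):
            k = int(rng.integers(0, 9))
            lineages = [Lineage(int(v)) for v in rng.integers(0, 4, k)]
            e, g = self._embryo_with_neighbors(lineages)
            n_epi = sum(1 for lg in lineages if lg == Lineage.EPI)
            n_und = sum(1 for lg in lineages if lg == Lineage.UNDETERMINED_ICM)
            n_pre = sum(1 for lg in lineages if lg == Lineage.PRE)
            n_icm = n_epi + n_und + n_pre
            expected = (n_epi + n_und) / n_icm if n_icm else 0.0
            assert rule2_pre_probability(e, 0, rc, graph=g) == pytest.approx(expected)

    def test_modes_clamp_fates(self):
        for mode, target in (("no_fgf", Lineage.EPI), ("excess_fgf", Lineage.PRE)):
            e, g = self._embryo_with_neighbors([Lineage.EPI, Lineage.PRE])
            j = divide_cell(e, 0)
            apply_rule2_fate(e, 0, j, RuleConfig(rule2_mode=mode), graph=g)
            assert Lineage(int(e.lin[0])) == target
            assert Lineage(int(e.lin[j])) == target


class TestRule3:
    def test_sets_flags(self):
        e = build_embryo([((0, 0), Lineage.EPI)])
        apply_rule3_adhesion(e, RuleConfig())
        assert e.rule3_active and not e.rule3_neutralized
        e2 = build_embryo([((0, 0), Lineage.EPI)])
        apply_rule3_adhesion(e2, RuleConfig(rule3_mode="neutralized"))
        assert e2.rule3_active and e2.rule3_neutralized


class TestRule4:
    def _pre_with_neighbors(self, lineages):
        cells = [((0.0, 0.0), Lineage.PRE)]
        for k, lg in enumerate(lineages):
            th = 2 * np.pi * k / len(lineages)
            cells.append(((2.2 * np.cos(th), 2.2 * np.sin(th)), lg))
        e = build_embryo(cells)
        g = NeighborGraph(adjacency={0: list(range(1, len(cells))),
                                     **{i: [0] for i in range(1, len(cells))}})
        return e, g

    def test_four_epi_neighbors_trigger_apoptosis(self):
        e, g = self._pre_with_neighbors([Lineage.EPI] * 4)
        assert deep_pre_indices(e, graph=g) == [0]
        _, n = apply_rule4_apoptosis(e, RuleConfig(), graph=g)
        assert n == 1
        assert int(Lineage.PRE) not in e.lineages

    def test_three_epi_neighbors_survive(self):
        # 3 is not > 3: the boundary case is kept
        e, g = self._pre_with_neighbors([Lineage.EPI] * 3 + [Lineage.PRE] * 2)
        assert deep_pre_indices(e, graph=g) == []
        _, n = apply_rule4_apoptosis(e, RuleConfig(), graph=g)
        assert n == 0

    def test_te_neighbors_not_counted_as_precursors(self):
        e, g = self._pre_with_neighbors([Lineage.EPI] * 3 + [Lineage.TE] * 3)
        # TE neighbors need polarity; rebuild with polarity vectors
        cells = [((0.0, 0.0), Lineage.PRE)]
        lineages = [Lineage.EPI] * 3 + [Lineage.TE] * 3
        for k, lg in enumerate(lineages):
            th = 2 * np.pi * k / 6
            pol = (np.cos(th), np.sin(th)) if lg == Lineage.TE else None
            cells.append(((2.2 * np.cos(th), 2.2 * np.sin(th)), lg, pol))
        e = build_embryo(cells)
        assert deep_pre_indices(e, graph=g) == []

    def test_epi_apoptosis_variant_removes_fraction(self):
        cells = [((2.2 * k, 0.0), Lineage.EPI) for k in range(10)]
        e = build_embryo(cells, seed=3)
        g = NeighborGraph(adjacency={i: [] for i in range(10)})
        _, n = apply_rule4_apoptosis(
            e, RuleConfig(epi_apoptosis_fraction=0.2), graph=g)
        assert n == 2
        assert e.n == 8
        assert e.apoptosis_count == 2
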