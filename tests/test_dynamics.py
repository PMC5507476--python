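import numpy as np
import pytest

from blastosim import (IntegratorState, Lineage, ModelParams,
                       equilibrium_distance, relax, step_positions,
                       total_energy)
from conftest import build_embryo, te_ring_cells


def quiet_integrator(seed=0, dt=0.1):
    return IntegratorState(dt=dt, noise_sd_position=0.0, noise_sd_angle=0.0,
                           rng=np.random.default_rng(seed))


class TestPositionSteps:
    def test_equilibrium_pair_is_a_fixed_point(self):
        d_star = equilibrium_distance(0.6, 5.0)
        e = build_embryo([((0, 0), Lineage.EPI), ((d_star, 0), Lineage.EPI)])
        before = e.positions.copy()
        step_positions(e, quiet_integrator(), n_steps=10)
        assert np.abs(e.positions - before).max() < 1e-9

    def test_close_pair_separates_monotonically(self):
        e = build_embryo([((0, 0), Lineage.EPI), ((1.5, 0), Lineage.EPI)])
        integ = quiet_integrator()
        d_prev = 1.5
        for _ in range(10):
            step_positions(e, integ, n_steps=10)
            d = np.linalg.norm(e.pos[1] - e.pos[0])
            assert d > d_prev
            d_prev = d

    def test_noise_displacement_variance(self):
        # isolated cells: displacement over n steps ~ Normal(0, n * sd^2)
        n_cells, n_steps, sd = 25, 4000, 1e-3
        cells = [((1000.0 * k, 0.0), Lineage.EPI) for k in range(n_cells)]
        e = build_embryo(cells, seed=5)
        before = e.positions.copy()
        integ = IntegratorState(dt=0.1, noise_sd_position=sd,
                                noise_sd_angle=0.0,
                                rng=np.random.default_rng(5))
        step_positions(e, integ, n_steps=n_steps)
        disp = (e.positions - before).ravel()
        var = disp.var()
        expected = n_steps * sd * sd
        # 50 samples of a chi^2-distributed variance estimate
        assert expected * 0.5 < var < expected * 1.7


class TestPolaritySteps:
    def test_aligned_te_pair_is_fixed(self):
        pol = np.array([0.0, 1.0])
        e = build_embryo([((0, 0), Lineage.TE, pol), ((1.6, 0), Lineage.TE, pol)])
        step_positions(e, quiet_integrator(), n_steps=20)
        assert np.abs(e.polarities - pol).max() < 1e-9

    def test_misaligned_angles_converge(self):
        a1, a2 = 0.0, 0.2
        cells = [((0, 0), Lineage.TE, (np.cos(a1), np.sin(a1))),
                 ((1.6, 0), Lineage.TE, (np.cos(a2), np.sin(a2)))]
        e = build_embryo(cells)
        integ = quiet_integrator()
        gap_prev = a2 - a1
        for _ in range(5):
            step_positions(e, integ, n_steps=20)
            ang = np.arctan2(e.polarities[:, 1], e.polarities[:, 0])
            gap = abs(ang[1] - ang[0])
            assert gap < gap_prev
            gap_prev = gap

    def test_isolated_te_polarity_random_walk_scale(self):
        n_cells, n_steps = 30, 2000
        sd = np.pi * 1e-3
        cells = [((1000.0 * k, 0.0), Lineage.TE, (1.0, 0.0))
                 for k in range(n_cells)]
        e = build_embryo(cells, seed=9)
        integ = IntegratorState(dt=0.1, noise_sd_position=0.0,
                                noise_sd_angle=sd,
                                rng=np.random.default_rng(9))
        step_positions(e, integ, n_steps=n_steps)
        ang = np.arctan2(e.polarities[:, 1], e.polarities[:, 0])
        var = ang.var()
        expected = n_steps * sd * sd
        assert expected * 0.4 < var < expected * 2.0


class TestRelax:
    def test_zero_steps_is_identity(self):
        e = build_embryo([((0, 0), Lineage.EPI), ((1.4, 0), Lineage.EPI)])
        before = e.positions.copy()
        steps, disp = relax(e, n_steps=0)
        assert steps == 0
        assert np.array_equal(e.positions, before)

    def test_random_cloud_converges_without_noise(self):
        rng = np.random.default_rng(4)
        cells = [(rng.uniform(0, 6, 2), Lineage.UNDETERMINED_ICM)
                 for _ in range(10)]
        e = build_embryo(cells, rule1_done=False)
        steps, disp = relax(e, n_steps=5000, integrator=quiet_integrator(4),
                            tol=1e-4, noise=False)
        assert disp < 1e-4

    def test_energy_nonincreasing_under_noise_free_descent(self):
        params = ModelParams(nearest_neighbor_interactions=False,
                             icm_interaction="cutoff")
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 12))
            cells = [(rng.uniform(0, 7, 2), Lineage.UNDETERMINED_ICM)
                     for _ in range(n)]
            e = build_embryo(cells, params=params, rule1_done=False)
            energy = total_energy(e)
            for _ in range(5):
                relax(e, n_steps=100, integrator=quiet_integrator(seed),
                      tol=0.0, noise=False)
                new_energy = total_energy(e)
                assert new_energy <= energy + 1e-9
                energy = new_energy

    def test_te_ring_persists_for_many_steps(self):
        # radial-polarity ring of 16 circles: the polar sheet configuration
        # is stable; no circle strays by more than a radius over 1e4 steps
        radius = 16 * 1.6 / (2 * np.pi)
        e = build_embryo(te_ring_cells(16, radius), seed=2)
        r0 = np.linalg.norm(e.positions - e.positions.mean(0), axis=1)
        integ = IntegratorState(rng=np.random.default_rng(2))
        for _ in range(10):
            relax(e, n_steps=1000, integrator=integ, tol=0.0)
        r1 = np.linalg.norm(e.positions - e.positions.mean(0), axis=1)
        assert np.abs(r1 - r0).max() < 1.0
        d = np.linalg.norm(e.positions[:, None] - e.positions[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min(axis=1).max() < 2.5  # ring never tears

    def test_bitwise_determinism_for_equal_seeds(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            pos_rng = np.random.default_rng(1)
            cells = [(pos_rng.uniform(0, 6, 2), Lineage.UNDETERMINED_ICM)
                     for _ in range(8)]
            e = build_embryo(cells, rule1_done=False)
            e.rng = rng
            relax(e, n_steps=500,
                  integrator=IntegratorState(rng=rng), tol=0.0)
            return e.positions.copy()
        assert np.array_equal(run(123), run(123))
        assert not np.array_equal(run(123), run(124))
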