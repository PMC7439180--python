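"""Genetic-algorithm encoding, operators, sampling region and recovery."""

import numpy as np
import pytest

from unitedcells import (
    Arena,
    GaConfig,
    GridParams,
    crossover,
    decode,
    ga_optimize,
    grid_rate,
    mutate,
    param_ranges,
    rate_map,
    sampling_region_cells,
    sampling_region_mask,
)
from unitedcells.ga_fit import fitness, random_population

ARENA = Arena(80.0, 60.0)
RANGES = param_ranges(ARENA)


class TestDecode:
    def test_all_zero_gives_lower_bounds(self):
        params = decode(np.zeros(50, dtype=np.uint8), RANGES, 10)
        assert np.allclose(params, RANGES[:, 0])

    def test_all_one_gives_upper_bounds(self):
        params = decode(np.ones(50, dtype=np.uint8), RANGES, 10)
        assert np.allclose(params, RANGES[:, 1])
        assert params[4] == pytest.approx(2 * np.pi)

    def test_linear_mapping_of_omega_block(self):
        bits = np.zeros(50, dtype=np.uint8)
        bits[40] = 1  # MSB of the omega block: u = 512
        params = decode(bits, RANGES, 10)
        assert params[4] == pytest.approx(512.0 / 1023.0 * 2 * np.pi)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode(np.zeros(49, dtype=np.uint8), RANGES, 10)


class TestOperators:
    def test_crossover_pc_zero_copies(self):
        rng = np.random.default_rng(0)
        p1 = np.array([0, 0, 1, 1], dtype=np.uint8)
        p2 = np.array([1, 1, 0, 0], dtype=np.uint8)
        c1, c2 = crossover(p1, p2, 0.0, rng)
        assert np.array_equal(c1, p1) and np.array_equal(c2, p2)

    def test_crossover_preserves_alleles(self):
        rng = np.random.default_rng(1)
        p1 = rng.integers(0, 2, 50, dtype=np.uint8)
        p2 = rng.integers(0, 2, 50, dtype=np.uint8)
        for _ in range(20):
            c1, c2 = crossover(p1, p2, 1.0, rng)
            # per locus the children's bits are a permutation of the parents'
            assert np.array_equal(np.sort(np.stack([c1, c2]), axis=0),
                                  np.sort(np.stack([p1, p2]), axis=0))

    def test_mutate_pm_zero_identity(self):
        rng = np.random.default_rng(2)
        c = rng.integers(0, 2, 50, dtype=np.uint8)
        assert np.array_equal(mutate(c, 0.0, rng), c)

    def test_mutate_expected_flips(self):
        rng = np.random.default_rng(3)
        c = np.zeros(50, dtype=np.uint8)
        flips = sum(mutate(c, 0.1, rng).sum() for _ in range(20000))
        # per-chromosome normalization: E[flips per chromosome] = pm
        assert flips / 20000 == pytest.approx(0.1, rel=0.15)

    def test_mutate_preserves_length(self):
        rng = np.random.default_rng(4)
        assert mutate(np.zeros(50, dtype=np.uint8), 1.0, rng).shape == (50,)


class TestFitness:
    true = GridParams(max_rate=0.8, spacing=12.0, phase_x=10.0, phase_y=20.0,
                      orientation=1.0)

    def _log(self, n=64, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform([0, 0], [80, 60], size=(n, 2))
        return pos, grid_rate(self.true, pos)

    def test_exact_parameters_zero_fitness(self):
        pos, rates = self._log()
        f = fitness(self.true.as_array()[None, :], pos, rates)
        assert f[0] == pytest.approx(0.0, abs=1e-18)

    def test_constant_offset(self):
        pos, rates = self._log(n=50)
        f = fitness(self.true.as_array()[None, :], pos, rates + 0.1)
        assert f[0] == pytest.approx(50 * 0.1**2)

    def test_order_invariance(self):
        pos, rates = self._log()
        perm = np.random.default_rng(1).permutation(len(pos))
        f1 = fitness(self.true.as_array()[None, :], pos, rates)
        f2 = fitness(self.true.as_array()[None, :], pos[perm], rates[perm])
        assert f1[0] == pytest.approx(f2[0])

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            fitness(self.true.as_array()[None, :], np.empty((0, 2)),
                    np.empty(0))


class TestSamplingRegion:
    def test_cell_classification(self, tiny_pmap):
        n = len(tiny_pmap)
        e1 = np.zeros(n)
        e2 = np.zeros(n)
        e1[3] = 1.2  # above Psi = 1 in one vector
        e2[5] = 0.9  # never above
        strong = sampling_region_cells([e1, e2], 1.0)
        assert strong[3] and not strong[5]
        assert strong.sum() == 1

    def test_region_is_union_of_halfmax_disks(self, tiny_pmap):
        n = len(tiny_pmap)
        E = np.zeros(n)
        E[0] = 2.0
        center = tiny_pmap.centers[0]
        r = tiny_pmap.half_max_radii[0]
        inside = center + [0.9 * r, 0.0]
        outside = center + [1.1 * r, 0.0]
        mask = sampling_region_mask(np.vstack([inside, outside]),
                                    tiny_pmap, [E], 1.0)
        assert mask[0] and not mask[1]

    def test_no_strong_cells_empty_region(self, tiny_pmap):
        mask = sampling_region_mask(
            np.array([[1.0, 1.0]]), tiny_pmap, [np.zeros(len(tiny_pmap))], 1.0
        )
        assert not mask[0]


class TestGaOptimize:
    def test_elitism_on_fixed_landscape(self):
        """With the same records every generation, the best fitness of the
        selected population never increases (mu+lambda selection)."""
        rng = np.random.default_rng(7)
        pos = rng.uniform([0, 0], [80, 60], size=(40, 2))
        true = GridParams(max_rate=1.0, spacing=15.0, phase_x=30.0,
                          phase_y=20.0, orientation=0.5)
        rates = grid_rate(true, pos)
        cfg = GaConfig(n_pop=20, k_records=40, budget=1.0)
        # replay the same 40 records for 30 generations
        rec_pos = np.tile(pos, (30, 1))
        rec_rates = np.tile(rates, 30)
        res = ga_optimize(rec_pos, rec_rates, RANGES, cfg, rng)
        hist = np.array(res.best_fitness)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_determinism(self):
        rng_pos = np.random.default_rng(8)
        pos = np.column_stack([rng_pos.uniform(0, 80, 4000),
                               rng_pos.uniform(0, 10, 4000)])
        true = GridParams(max_rate=1.0, spacing=12.0, phase_x=30.0,
                          phase_y=4.0, orientation=0.4)
        rates = grid_rate(true, pos)
        cfg = GaConfig(n_pop=20, k_records=100)
        r1 = ga_optimize(pos, rates, RANGES, cfg, np.random.default_rng(5))
        r2 = ga_optimize(pos, rates, RANGES, cfg, np.random.default_rng(5))
        assert r1.params == r2.params
        assert r1.best_fitness == r2.best_fitness

    def test_budget_too_small(self):
        cfg = GaConfig(k_records=100)
        with pytest.raises(ValueError):
            ga_optimize(np.zeros((50, 2)), np.zeros(50), RANGES, cfg,
                        np.random.default_rng(0))

    def test_fixed_omega_held(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform([0, 0], [80, 60], size=(600, 2))
        true = GridParams(max_rate=1.0, spacing=15.0, phase_x=30.0,
                          phase_y=20.0, orientation=0.5)
        rates = grid_rate(true, pos)
        cfg = GaConfig(n_pop=20, k_records=100)
        res = ga_optimize(pos, rates, RANGES, cfg, rng, fixed_omega=1.234)
        assert res.params.orientation == pytest.approx(1.234)

    def test_parameter_recovery_from_boundary_band(self):
        """The generating parameters are the oracle: sampling a known grid
        field only within a 10 m wall band, the GA recovers the spacing
        within 5%, the direction modulo pi/3 within 0.05 rad, and the
        whole-arena rate map to correlation > 0.95."""
        true = GridParams(max_rate=1.0, spacing=12.0, phase_x=30.0,
                          phase_y=4.0, orientation=0.4)
        rng = np.random.default_rng(5)
        pos = np.column_stack([rng.uniform(0, 80, 60000),
                               rng.uniform(0, 10, 60000)])
        rates = grid_rate(true, pos)
        res = ga_optimize(pos, rates, RANGES, GaConfig(), rng)
        fit = res.params
        assert fit.spacing == pytest.approx(12.0, rel=0.05)
        d_om = (fit.orientation - 0.4) % (np.pi / 3)
        assert min(d_om, np.pi / 3 - d_om) < 0.05
        corr = np.corrcoef(
            rate_map(true, ARENA, 0.5).values.ravel(),
            rate_map(fit, ARENA, 0.5).values.ravel(),
        )[0, 1]
        assert corr > 0.95
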