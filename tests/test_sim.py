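"""Stochastic split-dish model: generative steps and overlap accounting."""
import numpy as np
import pytest

from clonetrace import sim
from clonetrace.sim import Population, SimParams


@pytest.fixture
def rng0():
    return np.random.default_rng(0)


class TestInitPopulation:
    def test_effective_cell_count_formula(self, rng0):
        pop = sim.init_population(170_000, 0.89, 8_000_000, rng0)
        assert pop.n_clones == round(170_000 * (1 - np.exp(-0.89)))
        assert pop.n_clones == 100_189

    def test_high_moi_saturates(self, rng0):
        pop = sim.init_population(1000, 50.0, 10**9, rng0)
        assert pop.n_cells == 1000

    def test_integrations_zero_truncated(self, rng0):
        pop = sim.init_population(20_000, 0.63, 10**6, rng0)
        k_int = np.diff(pop.clone_offsets)
        assert k_int.min() >= 1
        mean_expected = 0.63 / (1 - np.exp(-0.63))  # zero-truncated Poisson mean
        assert np.mean(k_int) == pytest.approx(mean_expected, rel=0.02)

    def test_single_integration_mode(self, rng0):
        pop = sim.init_population(5_000, 2.0, 10**6, rng0, single_integration=True)
        assert np.all(np.diff(pop.clone_offsets) == 1)

    def test_birthday_collision_rate(self, rng0):
        """Barcode reuse between unrelated cells follows the birthday rate."""
        n0 = round(170_000 * (1 - np.exp(-0.89)))
        pop = sim.init_population(170_000, 0.89, 8_000_000, rng0,
                                  single_integration=True)
        collisions = n0 - np.unique(pop.clone_barcodes).size
        expected = n0**2 / (2 * 8_000_000)  # ~627
        assert collisions == pytest.approx(expected, rel=0.15)

    def test_no_infected_cells_rejected(self, rng0):
        with pytest.raises(ValueError, match="N0"):
            sim.init_population(1, 1e-9, 100, rng0)


class TestDivide:
    def test_all_cells_double(self, rng0):
        pop = sim.init_population(1000, 1.0, 10**6, rng0)
        out = sim.divide(pop, [0, 0, 1.0], rng0)
        assert out.n_cells == 2 * pop.n_cells
        assert np.all(out.cell_class == 2)

    def test_zero_progeny_empties_population(self, rng0):
        pop = sim.init_population(100, 1.0, 10**6, rng0)
        out = sim.divide(pop, [1.0], rng0)
        assert out.n_cells == 0

    def test_progeny_inherit_clone_barcodes(self, rng0):
        pop = sim.init_population(200, 1.0, 10**6, rng0)
        out = sim.divide(pop, [0, 0, 0, 1.0], rng0)
        # conservation: 3 progeny per founder, same clone ids
        assert np.all(np.bincount(out.cell_clone, minlength=pop.n_clones) == 3)

    def test_class_frequencies_match_distribution(self, rng0):
        p = np.asarray(sim.DEFAULT_PROGENY_DIST)
        pop = sim.init_population(200_000, 1.0, 10**8, rng0)
        out = sim.divide(pop, p, rng0)
        # founders with k progenies appear k times; recover founder fractions
        k = np.arange(9)
        counts = np.bincount(out.cell_class, minlength=9)
        founders = np.zeros(9)
        founders[1:] = counts[1:] / k[1:]
        frac = founders / pop.n_clones
        expected = p.copy()
        expected[0] = 0  # class-0 founders leave no cells
        assert np.allclose(frac[1:], expected[1:], atol=0.01)


class TestPlateAndCull:
    def test_uniform_dish_marginals(self, rng0):
        pop = sim.init_population(40_000, 1.0, 10**8, rng0)
        pop = sim.plate(pop, rng0)
        frac = np.bincount(pop.cell_dish, minlength=4) / pop.n_cells
        assert np.allclose(frac, 0.25, atol=0.01)

    def test_sister_split_frequency(self, rng0):
        pop = sim.init_population(50_000, 1.0, 10**9, rng0)
        pop = sim.divide(pop, [0, 0, 1.0], rng0)
        pop = sim.plate(pop, rng0)
        order = np.argsort(pop.cell_clone, kind="stable")
        dishes = pop.cell_dish[order].reshape(-1, 2)
        frac_split = np.mean(dishes[:, 0] != dishes[:, 1])
        assert frac_split == pytest.approx(0.75, abs=0.01)

    def test_plate_empty_population(self, rng0):
        pop = sim.init_population(100, 1.0, 10**6, rng0)
        pop = sim.divide(pop, [1.0], rng0)
        assert sim.plate(pop, rng0).n_cells == 0

    def test_cull_zero_is_identity(self, rng0):
        pop = sim.plate(sim.init_population(1000, 1.0, 10**6, rng0), rng0)
        out = sim.cull(pop, 0.0, rng0)
        assert out.n_cells == pop.n_cells

    def test_cull_removes_fixed_count_per_dish(self, rng0):
        pop = sim.plate(sim.init_population(8000, 9.0, 10**6, rng0), rng0)
        sizes = np.bincount(pop.cell_dish, minlength=4)
        out = sim.cull(pop, 0.5, rng0)
        out_sizes = np.bincount(out.cell_dish, minlength=4)
        assert np.all(out_sizes == sizes - np.round(0.5 * sizes).astype(int))

    def test_cull_survivors_unbiased(self, rng0):
        """Progeny-class proportions are preserved in expectation."""
        pop = sim.init_population(50_000, 1.0, 10**8, rng0)
        pop = sim.divide(pop, sim.DEFAULT_PROGENY_DIST, rng0)
        pop = sim.plate(pop, rng0)
        before = np.bincount(pop.cell_class, minlength=9) / pop.n_cells
        out = sim.cull(pop, 0.6, rng0)
        after = np.bincount(out.cell_class, minlength=9) / out.n_cells
        assert np.allclose(before, after, atol=0.01)


def _toy_population(dishes, k_int=1):
    """One clone with len(dishes) progenies in the given dishes."""
    n = len(dishes)
    return Population(
        clone_barcodes=np.arange(k_int, dtype=np.int64),
        clone_offsets=np.array([0, k_int], dtype=np.int64),
        cell_clone=np.zeros(n, dtype=np.int64),
        cell_class=np.full(n, n, dtype=np.int64),
        cell_dish=np.asarray(dishes, dtype=np.int64),
        cell_repro=np.zeros(n, dtype=bool),
    )


class TestReprogram:
    def test_full_heritability_forces_overlap(self, rng0):
        pop = _toy_population([0, 1])
        params = SimParams(
            n_seeded=10, moi=0.5, heritability=1.0, dish_targets=[1, 0, 0, 0]
        )
        counts = sim.reprogram(pop, params, rng0)
        assert counts.exactly[2] == 1
        assert counts.shared == 1

    def test_no_heritability_no_sibling_flag(self, rng0):
        pop = _toy_population([0, 1])
        params = SimParams(
            n_seeded=10, moi=0.5, heritability=0.0, dish_targets=[1, 0, 0, 0]
        )
        counts = sim.reprogram(pop, params, rng0)
        assert counts.n_reprogrammed == 1
        assert counts.shared == 0

    def test_zero_variance_targets_hit_quota_exactly(self, rng0):
        params = SimParams(
            n_seeded=40_000, moi=2.0, diversity=10**9, mu=50.0, si=0.0,
            heritability=0.0, single_integration=True,
        )
        pop = sim.init_population(40_000, 2.0, 10**9, rng0, single_integration=True)
        pop = sim.plate(pop, rng0)
        counts = sim.reprogram(pop, params, rng0)
        assert counts.per_dish_distinct.tolist() == [50, 50, 50, 50]

    def test_infeasible_quota_flagged(self, rng0):
        pop = _toy_population([0, 1])
        params = SimParams(
            n_seeded=10, moi=0.5, heritability=0.0, dish_targets=[5, 0, 0, 0]
        )
        counts = sim.reprogram(pop, params, rng0)
        assert counts.clamped

    def test_heritability_map_by_progeny_class(self, rng0):
        """Class-specific heritability hits only the configured class."""
        n_clones = 4000
        rng = np.random.default_rng(1)
        # clones of class 2 and class 4, two cells each in dishes 0/1
        pops = []
        classes = np.repeat([2, 4], n_clones // 2)
        cells = np.repeat(np.arange(n_clones), 2)
        pop = Population(
            clone_barcodes=np.arange(n_clones, dtype=np.int64),
            clone_offsets=np.arange(n_clones + 1, dtype=np.int64),
            cell_clone=cells,
            cell_class=np.repeat(classes, 2).astype(np.int64),
            cell_dish=np.tile([0, 1], n_clones).astype(np.int64),
            cell_repro=np.zeros(2 * n_clones, dtype=bool),
        )
        params = SimParams(
            n_seeded=10, moi=0.5, heritability={4: 1.0},
            dish_targets=[n_clones // 2, 0, 0, 0],
        )
        counts = sim.reprogram(pop, params, rng)
        # every stage-1 class-4 cell's sister reprogrammes; class-2 never
        assert counts.contribution_exactly2.get(2, 0) == 0
        assert counts.contribution_exactly2.get(4, 0) > 0


class TestRun:
    def test_seed_determinism(self, scaled_params):
        from dataclasses import replace

        params = replace(scaled_params, heritability=0.1, n_replicates=5)
        a = sim.run(params, 123).shared_counts
        b = sim.run(params, 123).shared_counts
        assert np.array_equal(a, b)

    def test_shared_counts_increase_with_heritability(self, scaled_params):
        from dataclasses import replace

        means = []
        for h in (0.0, 0.1, 0.3, 0.5):
            params = replace(scaled_params, heritability=h, n_replicates=8)
            means.append(sim.run(params, 7).shared_counts.mean())
        assert means == sorted(means)

    def test_dish_conservation(self, scaled_params):
        from dataclasses import replace

        params = replace(scaled_params, heritability=0.1, n_replicates=1)
        rng = np.random.default_rng(3)
        pop = sim.init_population(params.n_seeded, params.moi, params.diversity, rng)
        pop = sim.divide(pop, params.progeny_dist, rng)
        pop = sim.plate(pop, rng)
        pop = sim.cull(pop, params.loss, rng)
        assert np.bincount(pop.cell_dish, minlength=4).sum() == pop.n_cells

    def test_multi_integration_correction_factor(self, scaled_params):
        from dataclasses import replace

        params = replace(
            scaled_params, heritability=0.0, n_replicates=2,
            multi_integration_correction=True,
        )
        res = sim.run(params, 5)
        factor = 0.63 / (1 - np.exp(-0.63))
        for rep in res.replicates:
            assert rep.correction_factor == pytest.approx(factor)
            assert rep.corrected_shared == pytest.approx(rep.shared / factor)

    def test_fast_cycling_classes_dominate_double_overlaps(self, scaled_params):
        """Clones with many progenies contribute disproportionately to
        double overlaps relative to their population share."""
        from dataclasses import replace

        params = replace(scaled_params, heritability=0.1, n_replicates=10)
        res = sim.run(params, 99)
        p = np.asarray(sim.DEFAULT_PROGENY_DIST)
        # fraction of *cells* in classes > 4
        cell_frac = (p[5:] * np.arange(5, 9)).sum() / (p * np.arange(9)).sum()
        contrib = np.zeros(9)
        for rep in res.replicates:
            for k, v in rep.contribution_exactly2.items():
                contrib[k] += v
        share = contrib[5:].sum() / contrib.sum()
        assert share > cell_frac
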