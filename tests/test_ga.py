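import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qspkr.ga import (
    FitnessEngine,
    GAConfig,
    Population,
    chromosome_fitness,
    crossover,
    init_population,
    mutate,
    pair_term,
    run_ga,
    select_next_generation,
)
from qspkr.synthetic import SyntheticSpec, generate_dataset

from conftest import make_random_dataset


def naive_fitness(genes, dp, X, config):
    """Three-nested-loop reference implementation of the pairwise
    award/penalty fitness, independent of the vectorized engine."""
    total = 0.0
    n = len(dp)
    for k in range(X.shape[1]):
        if not genes[k]:
            continue
        for i in range(n - 1):
            for j in range(i + 1, n):
                if abs(dp[i] - dp[j]) >= config.epsilon:
                    total += -config.penalty
                else:
                    total += config.award - abs(X[i, k] - X[j, k])
    return total


class TestPairTerm:
    def test_penalty_branch(self):
        cfg = GAConfig()
        assert pair_term(0.3, 0.1, 0.2, 0.9, cfg) == -5.0

    def test_award_branch_identical_descriptors(self):
        cfg = GAConfig()
        assert pair_term(0.50, 0.55, 0.4, 0.4, cfg) == 5.0

    def test_award_branch_hand_value(self):
        cfg = GAConfig()
        assert pair_term(0.50, 0.55, 0.3, 0.8, cfg) == pytest.approx(4.5)

    def test_branch_switch_exactly_at_epsilon(self):
        cfg = GAConfig()
        assert pair_term(0.0, cfg.epsilon, 0.5, 0.5, cfg) == -cfg.penalty
        assert pair_term(0.0, np.nextafter(cfg.epsilon, 0), 0.5, 0.5, cfg) == 5.0


class TestChromosomeFitness:
    def test_worked_example_two_descriptors(self, tiny_dataset):
        # pairs: (a,b) similar, (a,c) and (b,c) dissimilar
        genes = np.array([1, 1], dtype=np.uint8)
        got = chromosome_fitness(genes, tiny_dataset, GAConfig())
        assert got == pytest.approx(-10.1)

    def test_worked_example_single_descriptor(self, tiny_dataset):
        genes = np.array([1, 0], dtype=np.uint8)
        got = chromosome_fitness(genes, tiny_dataset, GAConfig())
        assert got == pytest.approx(-5.1)

    def test_empty_chromosome_scores_zero(self, tiny_dataset):
        genes = np.zeros(2, dtype=np.uint8)
        assert chromosome_fitness(genes, tiny_dataset, GAConfig()) == 0.0

    def test_length_mismatch_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            chromosome_fitness(np.ones(5, dtype=np.uint8), tiny_dataset,
                               GAConfig())

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle_exactly_on_grid_instances(self, seed):
        # values on a 1/64 grid make every partial sum exactly representable,
        # so the vectorized engine and the naive loop must agree to the bit
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 10), rng.integers(1, 10)
        data = make_random_dataset(n, m, seed + 100, grid=64)
        cfg = GAConfig()
        genes = rng.integers(0, 2, size=m).astype(np.uint8)
        assert chromosome_fitness(genes, data, cfg) == naive_fitness(
            genes, data.dp, data.X, cfg)

    def test_matches_naive_oracle_on_continuous_instances(self):
        rng = np.random.default_rng(7)
        data = make_random_dataset(8, 6, 3)
        cfg = GAConfig()
        for _ in range(20):
            genes = rng.integers(0, 2, size=6).astype(np.uint8)
            assert chromosome_fitness(genes, data, cfg) == pytest.approx(
                naive_fitness(genes, data.dp, data.X, cfg), rel=1e-12)

    @given(st.integers(0, 2 ** 10 - 1), st.integers(0, 2 ** 10 - 1))
    def test_additive_over_disjoint_gene_sets(self, mask_a, mask_b):
        data = make_random_dataset(6, 10, 42, grid=64)
        cfg = GAConfig()
        a = np.array([(mask_a >> k) & 1 for k in range(10)], dtype=np.uint8)
        b = np.array([(mask_b >> k) & 1 for k in range(10)], dtype=np.uint8)
        b &= 1 - a  # force disjoint
        fa = chromosome_fitness(a, data, cfg)
        fb = chromosome_fitness(b, data, cfg)
        fab = chromosome_fitness(a | b, data, cfg)
        assert fab == pytest.approx(fa + fb, abs=1e-9)

    def test_penalty_per_pair_mode_counts_penalty_once(self, tiny_dataset):
        cfg = GAConfig(penalty_per_pair=True)
        genes = np.array([1, 1], dtype=np.uint8)
        # award terms 4.9 + 5.0, two dissimilar pairs penalised once each
        got = chromosome_fitness(genes, tiny_dataset, cfg)
        assert got == pytest.approx(4.9 + 5.0 - 2 * 5.0)


class TestInitPopulation:
    def test_full_scale_shape(self):
        pop = init_population(1481, GAConfig(seed=7))
        assert pop.chromosomes.shape == (500, 1481)
        assert set(np.unique(pop.chromosomes)) <= {0, 1}

    def test_same_seed_reproduces(self):
        a = init_population(100, GAConfig(seed=3))
        b = init_population(100, GAConfig(seed=3))
        np.testing.assert_array_equal(a.chromosomes, b.chromosomes)

    def test_genes_near_half_density(self):
        pop = init_population(1481, GAConfig(seed=7))
        assert abs(pop.chromosomes.mean() - 0.5) < 0.01

    def test_rejects_empty_descriptor_set(self):
        with pytest.raises(ValueError):
            init_population(0, GAConfig())


class TestCrossover:
    def test_hand_example_break_after_two(self):
        a = np.zeros(6, dtype=np.uint8)
        b = np.ones(6, dtype=np.uint8)

        class FixedRng:
            def integers(self, lo, hi=None):
                return 2

        c1, c2 = crossover(a, b, FixedRng())
        np.testing.assert_array_equal(c1, [0, 0, 1, 1, 1, 1])
        np.testing.assert_array_equal(c2, [1, 1, 0, 0, 0, 0])

    def test_identical_parents_fixed_point(self):
        rng = np.random.default_rng(0)
        p = rng.integers(0, 2, 30).astype(np.uint8)
        c1, c2 = crossover(p, p.copy(), rng)
        np.testing.assert_array_equal(c1, p)
        np.testing.assert_array_equal(c2, p)

    @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1),
           st.integers(0, 10 ** 6))
    def test_bit_multiset_conserved(self, xa, xb, seed):
        a = np.array([(xa >> k) & 1 for k in range(16)], dtype=np.uint8)
        b = np.array([(xb >> k) & 1 for k in range(16)], dtype=np.uint8)
        c1, c2 = crossover(a, b, np.random.default_rng(seed))
        assert c1.sum() + c2.sum() == a.sum() + b.sum()
        assert c1.shape == c2.shape == (16,)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover(np.zeros(3, dtype=np.uint8), np.zeros(4, dtype=np.uint8),
                      np.random.default_rng(0))


class TestMutate:
    def test_probability_zero_never_changes(self):
        rng = np.random.default_rng(1)
        chrom = rng.integers(0, 2, 50).astype(np.uint8)
        cfg = GAConfig(mutation_probability=0.0)
        for _ in range(200):
            np.testing.assert_array_equal(mutate(chrom, cfg, rng), chrom)

    def test_probability_one_flips_exactly_one_bit(self):
        rng = np.random.default_rng(2)
        chrom = rng.integers(0, 2, 50).astype(np.uint8)
        cfg = GAConfig(mutation_probability=1.0)
        for _ in range(200):
            out = mutate(chrom, cfg, rng)
            assert int((out != chrom).sum()) == 1

    @given(st.integers(0, 10 ** 6))
    def test_hamming_distance_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        chrom = rng.integers(0, 2, 64).astype(np.uint8)
        out = mutate(chrom, GAConfig(), rng)
        assert int((out != chrom).sum()) in (0, 1)

    def test_empirical_rate_matches_setting(self):
        rng = np.random.default_rng(1)
        chrom = np.zeros(1481, dtype=np.uint8)
        cfg = GAConfig()
        n = 20_000
        changed = sum(
            int((mutate(chrom, cfg, rng) != chrom).any()) for _ in range(n))
        # 99% binomial CI half-width at n=20k is ~0.0055
        assert abs(changed / n - cfg.mutation_probability) < 0.006


class TestEvolutionLoop:
    def _evaluated(self, data, cfg):
        eng = FitnessEngine(data, cfg)
        pop = init_population(data.n_descriptors, cfg)
        pop.fitness = eng.population_fitness(pop.chromosomes)
        return eng, pop

    def test_population_size_preserved(self):
        data = make_random_dataset(8, 30, 1)
        cfg = GAConfig(population_size=40, seed=5)
        eng, pop = self._evaluated(data, cfg)
        nxt = select_next_generation(pop, eng, cfg, np.random.default_rng(0))
        assert nxt.chromosomes.shape == (40, 30)
        assert nxt.generation == 1

    @pytest.mark.parametrize("strategy", ["plus", "generational"])
    def test_best_fitness_never_decreases(self, strategy):
        data = make_random_dataset(10, 25, 2)
        cfg = GAConfig(population_size=30, seed=9, survivor_strategy=strategy,
                       elitism_count=1, gene_limit=1)
        eng, pop = self._evaluated(data, cfg)
        rng = np.random.default_rng(3)
        best = -np.inf
        for _ in range(15):
            cur = float(pop.fitness.max())
            assert cur >= best
            best = max(best, cur)
            pop = select_next_generation(pop, eng, cfg, rng)
            pop.fitness = eng.population_fitness(pop.chromosomes)

    def test_same_seed_same_generation_five(self):
        data = make_random_dataset(8, 20, 4)
        cfg = GAConfig(population_size=20, seed=11)

        def gen5():
            eng, pop = self._evaluated(data, cfg)
            rng = np.random.default_rng(7)
            for _ in range(5):
                pop.fitness = eng.population_fitness(pop.chromosomes)
                pop = select_next_generation(pop, eng, cfg, rng)
            return pop.chromosomes

        np.testing.assert_array_equal(gen5(), gen5())


class TestRunGA:
    def test_gene_limit_termination_and_determinism(self):
        data, _ = generate_dataset(
            SyntheticSpec(n_compounds=20, n_descriptors=60, n_informative=3,
                          seed=5))
        cfg = GAConfig(population_size=60, gene_limit=8, max_generations=400,
                       seed=5, patience=20)
        r1 = run_ga(data, cfg)
        r2 = run_ga(data, cfg)
        assert r1.selected_indices == r2.selected_indices
        assert len(r1.selected_indices) <= 8
        assert r1.selected_indices == sorted(r1.selected_indices)
        assert r1.fitness_trajectory == r2.fitness_trajectory

    def test_degenerate_pk_spread_warns_but_runs(self):
        # every pair differs by >= epsilon: the award branch never fires
        data = make_random_dataset(4, 30, 8)
        data.dp = np.array([0.0, 0.3, 0.6, 0.9])
        cfg = GAConfig(population_size=20, gene_limit=5, max_generations=30,
                       seed=1, patience=5)
        res = run_ga(data, cfg)
        assert any("award branch" in w for w in res.warnings)

    def test_requires_enough_descriptors(self, tiny_dataset):
        with pytest.raises(ValueError):
            run_ga(tiny_dataset, GAConfig(gene_limit=15))

    def test_constant_descriptors_never_selected(self):
        data = make_random_dataset(12, 40, 6)
        data.constant_descriptors = np.zeros(40, dtype=bool)
        data.constant_descriptors[[3, 17]] = True
        data.X[:, [3, 17]] = 0.0
        cfg = GAConfig(population_size=30, gene_limit=6, max_generations=300,
                       seed=2, patience=10)
        res = run_ga(data, cfg)
        assert 3 not in res.selected_indices
        assert 17 not in res.selected_indices
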