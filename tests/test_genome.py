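import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdea.genome import (
    DS_BOUNDS,
    ORI_BOUNDS,
    Chromosome,
    GeneticParams,
    InvalidConfigError,
    UnscoredPopulationError,
    axis_angle,
    crossover,
    init_population,
    mutate,
    next_generation,
    random_chromosome,
    tournament_select,
)
from .conftest import scored_population


class TestRandomChromosome:
    def test_genes_within_bounds(self, rng):
        for _ in range(1000):
            c = random_chromosome(rng)
            assert DS_BOUNDS[0] <= c.ds <= DS_BOUNDS[1]
            assert ORI_BOUNDS[0] <= c.ori <= ORI_BOUNDS[1]
            assert c.bina in (-1, 1)

    def test_deterministic_under_reseeding(self):
        a = random_chromosome(np.random.default_rng(7))
        b = random_chromosome(np.random.default_rng(7))
        assert a == b

    def test_uniform_mean_ds(self, rng):
        draws = [random_chromosome(rng).ds for _ in range(10_000)]
        assert math.isclose(np.mean(draws), 2.125, abs_tol=0.05)


class TestInitPopulation:
    @pytest.mark.parametrize("size", [48, 4])
    def test_sizes(self, rng, size):
        pop = init_population(rng, size)
        assert len(pop.members) == size
        assert pop.generation_index == 1
        assert all(m.fitness is None for m in pop.members)
        assert all(m.provenance == "offspring-unscored" for m in pop.members)

    def test_too_small_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            init_population(rng, 3)


class TestTournamentSelect:
    def test_two_fittest_of_sample(self, rng):
        pop = scored_population([0.9, 0.5, 0.1], rng)
        p1, p2 = tournament_select(pop, GeneticParams(), rng)
        assert (p1.fitness, p2.fitness) == (0.9, 0.5)

    def test_tie_broken_by_earlier_index(self, rng):
        pop = scored_population([0.4, 0.4, 0.4], rng)
        p1, p2 = tournament_select(pop, GeneticParams(), rng)
        assert p1 is pop.members[0] and p2 is pop.members[1]

    def test_unscored_population_rejected(self, rng):
        pop = init_population(rng, 8)
        with pytest.raises(UnscoredPopulationError):
            tournament_select(pop, GeneticParams(), rng)

    def test_top_member_parent_frequency_matches_inclusion_probability(self, rng):
        # rank-1 of 48 is a parent iff sampled: P = 3/48 for a size-3 sample
        pop = scored_population(np.linspace(0.99, 0.01, 48), rng)
        best = pop.members[0]
        hits = sum(
            best in tournament_select(pop, GeneticParams(), rng)
            for _ in range(10_000)
        )
        p = 3 / 48
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(hits / 10_000 - p) < 4 * se


class TestCrossover:
    def test_identical_parents_fixed_point(self, rng):
        c = Chromosome(ds=1.5, ori=30.0, bina=1)
        child = crossover(c, c, rng)
        assert child.ds == pytest.approx(1.5) and child.ori == pytest.approx(30.0)

    def test_blend_stays_within_parent_range(self, rng):
        p1 = Chromosome(ds=0.0, ori=0.0, bina=1)
        p2 = Chromosome(ds=4.25, ori=90.0, bina=-1)
        for _ in range(200):
            child = crossover(p1, p2, rng)
            assert 0.0 <= child.ds <= 4.25
            assert child.bina in (-1, 1)

    def test_mean_child_is_parent_midpoint(self, rng):
        p1 = Chromosome(ds=1.0, ori=45.0, bina=1)
        p2 = Chromosome(ds=3.0, ori=45.0, bina=1)
        mean_ds = np.mean([crossover(p1, p2, rng).ds for _ in range(10_000)])
        assert math.isclose(mean_ds, 2.0, abs_tol=0.05)


class TestMutate:
    def test_zero_probability_is_identity(self, rng):
        params = GeneticParams(mutation_prob_per_gene=0.0, bina_flip_prob=0.0)
        c = Chromosome(ds=2.0, ori=45.0, bina=-1)
        assert mutate(c, params, rng) == c

    def test_reflection_keeps_genes_in_bounds(self, rng):
        params = GeneticParams(mutation_prob_per_gene=1.0, mutation_sigma_fraction=0.5)
        for start in (0.0, 4.25):
            for _ in range(500):
                m = mutate(Chromosome(ds=start, ori=0.0, bina=1), params, rng)
                assert DS_BOUNDS[0] <= m.ds <= DS_BOUNDS[1]
                assert ORI_BOUNDS[0] <= m.ori <= ORI_BOUNDS[1]

    def test_change_rate_matches_probability(self, rng):
        params = GeneticParams(mutation_prob_per_gene=0.1, bina_flip_prob=0.0)
        c = Chromosome(ds=2.0, ori=45.0, bina=1)
        n = 10_000
        changed = sum(mutate(c, params, rng).ds != c.ds for _ in range(n))
        se = math.sqrt(0.1 * 0.9 / n)
        assert abs(changed / n - 0.1) < 4 * se


class TestNextGeneration:
    def test_size_constant_and_survivor_count(self, rng):
        pop = scored_population(rng.uniform(0, 1, 48), rng)
        nxt = next_generation(pop, GeneticParams(), rng)
        assert len(nxt.members) == 48
        assert nxt.generation_index == 2
        # 16 fittest survive with their scores; 32 offspring arrive unscored
        assert sum(m.fitness is not None for m in nxt.members) == 16
        assert sum(m.fitness is None for m in nxt.members) == 32

    def test_fittest_member_survives_unchanged(self, rng):
        pop = scored_population(rng.uniform(0, 1, 48), rng)
        best = max(pop.members, key=lambda m: m.fitness)
        nxt = next_generation(pop, GeneticParams(), rng)
        assert any(
            m.chromosome == best.chromosome and m.fitness == best.fitness
            for m in nxt.members
        )

    def test_unscored_rejected(self, rng):
        with pytest.raises(UnscoredPopulationError):
            next_generation(init_population(rng, 48), GeneticParams(), rng)


@pytest.mark.parametrize(
    "ori,bina,expected", [(0.0, -1, 0.0), (90.0, 1, 90.0), (45.0, -1, -45.0)]
)
def test_axis_angle_sign_rule(ori, bina, expected):
    assert axis_angle(Chromosome(ds=0.0, ori=ori, bina=bina)) == expected


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 2**31 - 1))
def test_gene_bounds_invariant_under_operator_chains(seed):
    """Any crossover/mutation sequence keeps every gene inside its bounds."""
    rng = np.random.default_rng(seed)
    params = GeneticParams(mutation_prob_per_gene=0.5, mutation_sigma_fraction=0.3)
    c1, c2 = random_chromosome(rng), random_chromosome(rng)
    for _ in range(20):
        child = mutate(crossover(c1, c2, rng), params, rng)
        assert DS_BOUNDS[0] <= child.ds <= DS_BOUNDS[1]
        assert ORI_BOUNDS[0] <= child.ori <= ORI_BOUNDS[1]
        assert child.bina in (-1, 1)
        c1, c2 = c2, child


def test_monotone_selection_pressure_without_mutation(rng):
    """Fitness strictly decreasing in ds + zero mutation => median ds never rises."""
    params = GeneticParams(mutation_prob_per_gene=0.0, bina_flip_prob=0.0)
    pop = init_population(rng, 48)
    medians = []
    for _ in range(15):
        for m in pop.members:
            m.fitness = 1.0 - m.chromosome.ds / 4.25
        medians.append(np.median([m.chromosome.ds for m in pop.members]))
        pop = next_generation(pop, params, rng)
    assert all(b <= a + 1e-12 for a, b in zip(medians, medians[1:]))


def test_neutral_drift_has_zero_mean_median_change(rng):
    """Equal fitness everywhere: mutation-driven drift, zero expected shift."""
    params = GeneticParams()
    deltas = []
    for _ in range(150):
        pop = init_population(rng, 48)
        before = np.median([m.chromosome.ds for m in pop.members])
        for m in pop.members:
            m.fitness = 0.5
        nxt = next_generation(pop, params, rng)
        deltas.append(np.median([m.chromosome.ds for m in nxt.members]) - before)
    deltas = np.asarray(deltas)
    assert abs(deltas.mean()) < 4 * deltas.std(ddof=1) / math.sqrt(len(deltas))
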