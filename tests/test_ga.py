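"""Evolutionary operators and the full GA loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spinorder as so
from spinorder.fitness import bipartition_colors, delta_population_scores, sms_population_scores
from spinorder.ga import (
    GAConfig,
    cluster_shuffle,
    elite_selection,
    evolve,
    init_population,
    order_crossover,
    select_mating_pool,
    swap_mutation,
)


class ScriptedRNG:
    """Deterministic stand-in for a Generator, fed explicit draws."""

    def __init__(self, integers=(), randoms=(), choices=()):
        self._int = list(integers)
        self._rand = list(randoms)
        self._choice = list(choices)

    def integers(self, low, high=None):
        return self._int.pop(0)

    def random(self):
        return self._rand.pop(0)

    def choice(self, a, size=None, replace=True, p=None):
        return np.asarray(self._choice.pop(0))


class TestInitPopulation:
    def test_shape_and_validity(self, rng):
        pop = init_population(6, 4, rng)
        assert pop.shape == (6, 4)
        for row in pop:
            assert sorted(row.tolist()) == [1, 2, 3, 4]

    def test_reproducible_under_seed(self):
        a = init_population(4, 3, np.random.default_rng(1))
        b = init_population(4, 3, np.random.default_rng(1))
        assert np.array_equal(a, b)

    def test_large_population(self, rng):
        assert init_population(200, 20, rng).shape == (200, 20)


class TestSelection:
    def test_degenerate_weight_selects_single_parent(self, rng):
        pop = np.array([[1, 2, 3], [3, 2, 1], [2, 1, 3]])
        pool = select_mating_pool(pop, np.array([0.0, 1.0, 0.0]), 5, rng)
        assert np.array_equal(pool, np.tile([3, 2, 1], (5, 1)))

    def test_equal_weights_are_uniform(self, rng):
        pop = np.arange(1, 5).reshape(4, 1) * np.ones((4, 3), dtype=int)
        counts = np.zeros(4)
        pool = select_mating_pool(pop, np.full(4, 0.25), 10000, rng)
        for k in range(4):
            counts[k] = np.sum(pool[:, 0] == k + 1)
        # binomial(10^4, 1/4): sd ~ 43; allow 5 sigma
        assert np.all(np.abs(counts - 2500) < 5 * 43.3)

    def test_elites_remain_eligible(self, rng):
        pop = np.array([[1, 2], [2, 1]])
        pool = select_mating_pool(pop, np.array([0.9, 0.1]), 50, rng)
        assert (pool[:, 0] == 1).sum() > 25  # elite row sampled too


class TestEliteSelection:
    def test_distinct_genotypes_preferred(self):
        pop = np.array([[1, 2, 3], [1, 2, 3], [3, 2, 1], [2, 3, 1]])
        scores = np.array([5.0, 5.0, 4.0, 3.0])
        elite = elite_selection(pop, scores, 2)
        assert elite.tolist() == [[1, 2, 3], [3, 2, 1]]

    def test_padding_when_not_enough_distinct(self):
        pop = np.array([[1, 2], [1, 2]])
        elite = elite_selection(pop, np.array([1.0, 1.0]), 2)
        assert elite.tolist() == [[1, 2], [1, 2]]


class TestOrderCrossover:
    def test_hand_traced_example(self):
        # segment (3,4) of p1 placed at child positions 2-3 (1-based)
        rng = ScriptedRNG(integers=[2, 2, 1])
        c1, c2 = order_crossover([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1], rng)
        assert c1.tolist() == [6, 3, 4, 5, 2, 1]
        assert sorted(c2.tolist()) == [1, 2, 3, 4, 5, 6]

    def test_full_segment_copies_parent(self):
        rng = ScriptedRNG(integers=[6, 0, 0])
        c1, c2 = order_crossover([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1], rng)
        assert c1.tolist() == [1, 2, 3, 4, 5, 6]
        assert c2.tolist() == [6, 5, 4, 3, 2, 1]

    def test_identical_parents_give_identical_children(self, rng):
        """The segment is re-placed at a random position, so identical
        parents need not reproduce themselves -- but both children coincide
        and stay permutations."""
        p = [4, 1, 3, 2]
        for _ in range(10):
            c1, c2 = order_crossover(p, p, rng)
            assert c1.tolist() == c2.tolist()
            assert sorted(c1.tolist()) == [1, 2, 3, 4]

    def test_identical_parents_reproduce_when_segment_keeps_position(self):
        rng = ScriptedRNG(integers=[2, 1, 1])  # segment [1,3] stays at idx 1-2
        c1, c2 = order_crossover([4, 1, 3, 2], [4, 1, 3, 2], rng)
        assert c1.tolist() == [4, 1, 3, 2] and c2.tolist() == [4, 1, 3, 2]

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            order_crossover([1, 2], [1, 2, 3], rng)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    @settings(max_examples=60, deadline=None)
    def test_children_are_permutations(self, seed, n):
        g = np.random.default_rng(seed)
        p1, p2 = g.permutation(n) + 1, g.permutation(n) + 1
        c1, c2 = order_crossover(p1, p2, g)
        assert sorted(c1.tolist()) == list(range(1, n + 1))
        assert sorted(c2.tolist()) == list(range(1, n + 1))


class TestClusterShuffle:
    def test_seeded_trace_swap_halves(self):
        # k=2 clusters, cut at 2, no reversals, swap clusters 0 and 1
        rng = ScriptedRNG(integers=[2], randoms=[0.9, 0.9], choices=[[2], [0, 1]])
        out = cluster_shuffle([1, 2, 3, 4], rng)
        assert out.tolist() == [3, 4, 1, 2]

    def test_seeded_trace_with_reversal(self):
        # reverse first cluster, then swap the two clusters
        rng = ScriptedRNG(integers=[2], randoms=[0.05, 0.9], choices=[[2], [0, 1]])
        out = cluster_shuffle([1, 2, 3, 4], rng)
        assert out.tolist() == [3, 4, 2, 1]

    def test_too_short(self, rng):
        with pytest.raises(ValueError):
            cluster_shuffle([1], rng)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 15))
    @settings(max_examples=60, deadline=None)
    def test_gene_multiset_preserved(self, seed, n):
        g = np.random.default_rng(seed)
        out = cluster_shuffle(g.permutation(n) + 1, g)
        assert sorted(out.tolist()) == list(range(1, n + 1))


class TestSwapMutation:
    def test_zero_rate_is_identity(self, rng):
        assert swap_mutation([3, 1, 2], 0.0, rng).tolist() == [3, 1, 2]

    def test_rate_one_two_genes_trace(self):
        # both genes trigger; partners 1 then 0 -> two swaps cancel
        rng = ScriptedRNG(integers=[1, 0], randoms=[0.0, 0.0])
        assert swap_mutation([1, 2], 1.0, rng).tolist() == [1, 2]

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0), st.integers(2, 15))
    @settings(max_examples=60, deadline=None)
    def test_gene_multiset_preserved(self, seed, m, n):
        g = np.random.default_rng(seed)
        out = swap_mutation(g.permutation(n) + 1, m, g)
        assert sorted(out.tolist()) == list(range(1, n + 1))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_pop": 3},
            {"n_pop": 10, "n_elite": 3},
            {"n_pop": 10, "n_elite": 10},
            {"mutation_rate": 1.5},
            {"cs_period": 0},
            {"generations": 0},
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GAConfig(**kw)

    def test_default_elite_is_ten_percent_even(self):
        assert GAConfig(n_pop=200).n_elite == 20
        assert GAConfig(n_pop=100).n_elite == 10


@pytest.fixture(scope="module")
def chain6_fitness():
    cm = so.chain(6, 0.5)
    return cm, (lambda pop: delta_population_scores(pop, cm, 0))


class TestEvolve:
    def test_best_is_monotone_under_elitism(self, chain6_fitness):
        _, fit = chain6_fitness
        cfg = GAConfig(n_pop=20, n_elite=2, mutation_rate=0.1, cs_period=5, generations=40, seed=3)
        res = evolve(cfg, fit, 6)
        best = res.history.best.to_numpy()
        assert (np.diff(best) >= -1e-12).all()

    def test_full_reproducibility(self, chain6_fitness):
        _, fit = chain6_fitness
        cfg = GAConfig(n_pop=20, n_elite=2, mutation_rate=0.1, cs_period=3, generations=25, seed=11)
        a, b = evolve(cfg, fit, 6), evolve(cfg, fit, 6)
        assert a.best_ordering == b.best_ordering
        assert a.history.equals(b.history)

    def test_recovers_exhaustive_optimum_six_site_chain(self, chain6_fitness):
        cm, fit = chain6_fitness
        records = so.exhaustive_scan(cm, 0)
        best_delta = max(r.delta_e for r in records)
        cfg = GAConfig(n_pop=40, n_elite=4, mutation_rate=0.05, cs_period=5,
                       generations=120, seed=5, target_score=best_delta)
        res = evolve(cfg, fit, 6)
        assert res.reached_target
        assert res.best_score == pytest.approx(best_delta)

    def test_crossover_only_run_plateaus(self, chain6_fitness):
        """m=0 and no CS: the run converges quickly and then the best score
        plateaus (pinned for a fixed seed; fully deterministic)."""
        _, fit = chain6_fitness
        cfg = GAConfig(n_pop=10, n_elite=2, mutation_rate=0.0, cs_period=None,
                       generations=60, seed=2)
        res = evolve(cfg, fit, 6)
        tail = res.history.best.to_numpy()[-10:]
        assert np.ptp(tail) == 0.0

    def test_sms_invalid_children_tolerated(self):
        cm = so.chain(8, 0.5)
        colors = bipartition_colors(cm)
        fit = lambda pop: sms_population_scores(pop, cm, colors)
        cfg = GAConfig(n_pop=30, n_elite=2, mutation_rate=0.05, cs_period=4,
                       generations=30, seed=9)
        res = evolve(cfg, fit, 8)
        assert np.isfinite(res.best_score)
        assert (res.history.n_valid >= 1).all()
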