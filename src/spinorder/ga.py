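"""Genetic algorithm over site orderings (permutation chromosomes).

The evolutionary loop per generation: score the population, copy the
``n_elite`` best *distinct* chromosomes unchanged, fill a mating pool of size
``n_pop - n_elite`` by roulette-wheel sampling (elites included, duplicates
expected), pair the pool randomly, produce children by order crossover --
or, on cluster-shuffle generations, by shuffling each pool member's site
clusters -- then swap-mutate the children.  Elitism makes the best score
monotonically non-decreasing.  Elites are deduplicated by genotype (ties
broken by first occurrence): keeping the best distinct orderings rather
than many copies of one preserves competing partial motifs, which is what
lets crossover assemble the global optimum instead of stagnating on the
first local one.  A single RNG stream seeded from the config
drives every draw in a fixed order (selection, pairing, crossover/CS,
mutation), so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fitness import selection_weights

__all__ = [
    "GAConfig",
    "GAResult",
    "init_population",
    "elite_selection",
    "select_mating_pool",
    "order_crossover",
    "cluster_shuffle",
    "swap_mutation",
    "evolve",
]

PopulationFitness = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
"""Maps a (M, N) matrix of 1-based orderings to (scores, valid) arrays."""


@dataclass
class GAConfig:
    """Evolutionary hyperparameters.

    ``n_pop`` and ``n_elite`` are kept even so the mating pool always pairs
    up; ``n_elite`` defaults to 10% of the population.  ``cs_period = p``
    replaces crossover by cluster shuffling every ``p``-th generation
    (``None`` disables it); mutation is applied on every child, cluster-
    shuffle generations included.
    """

    n_pop: int = 100
    n_elite: int | None = None
    mutation_rate: float = 0.05
    cs_period: int | None = 5
    cluster_reversal_prob: float = 0.1
    generations: int = 1000
    seed: int = 0
    target_score: float | None = None

    def __post_init__(self) -> None:
        if self.n_elite is None:
            self.n_elite = max(2, 2 * round(0.05 * self.n_pop))  # 10%, even
        if self.n_pop < 2 or self.n_pop % 2:
            raise ValueError("population size must be even and >= 2")
        if self.n_elite % 2 or not (0 < self.n_elite < self.n_pop):
            raise ValueError("elite count must be even and in (0, n_pop)")
        for name in ("mutation_rate", "cluster_reversal_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cs_period is not None and self.cs_period < 1:
            raise ValueError("cs_period must be a positive integer or None")
        if self.generations < 1:
            raise ValueError("need at least one generation")


@dataclass
class GAResult:
    best_ordering: tuple[int, ...]
    best_score: float
    history: pd.DataFrame = field(repr=False)
    generations_run: int = 0
    reached_target: bool = False


def init_population(n_pop: int, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random 1-based orderings, shape (n_pop, n_sites)."""
    if n_pop < 2:
        raise ValueError("population must contain at least 2 chromosomes")
    if n_sites < 1:
        raise ValueError("need at least one site")
    return np.array([rng.permutation(n_sites) + 1 for _ in range(n_pop)])


def elite_selection(pop: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """The ``k`` best distinct chromosomes (stable order, best first).

    Duplicated genotypes count once; if fewer than ``k`` distinct
    chromosomes exist the remainder is filled with copies of the best.
    """
    order = np.argsort(-scores, kind="stable")
    out: list[np.ndarray] = []
    seen: set[bytes] = set()
    for idx in order:
        key = pop[idx].tobytes()
        if key not in seen:
            seen.add(key)
            out.append(pop[idx].copy())
            if len(out) == k:
                break
    while len(out) < k:
        out.append(pop[order[0]].copy())
    return np.array(out)


def select_mating_pool(
    population: np.ndarray,
    weights: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Roulette-wheel sample ``k`` chromosomes with replacement."""
    idx = rng.choice(population.shape[0], size=k, replace=True, p=weights)
    return population[idx].copy()


def order_crossover(
    p1: Sequence[int], p2: Sequence[int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Order crossover for permutations.

    A random contiguous segment of the first parent is placed at a random
    position in the child; the remaining slots are filled left-to-right by
    scanning the second parent from its first gene and skipping genes
    already present.  Parent roles swap for the second child.  RNG draws:
    segment length, segment start, placement position (shared by both
    children).
    """
    p1 = np.asarray(p1, dtype=int)
    p2 = np.asarray(p2, dtype=int)
    if p1.shape != p2.shape:
        raise ValueError("parents must have equal length")
    n = p1.shape[0]
    length = int(rng.integers(1, n + 1))
    start = int(rng.integers(0, n - length + 1))
    place = int(rng.integers(0, n - length + 1))

    def make_child(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        child = np.zeros(n, dtype=int)
        seg = a[start : start + length]
        child[place : place + length] = seg
        present = set(seg.tolist())
        fill = (g for g in b if g not in present)
        for k in range(n):
            if child[k] == 0:
                child[k] = next(fill)
        return child

    return make_child(p1, p2), make_child(p2, p1)


def cluster_shuffle(
    chrom: Sequence[int],
    rng: np.random.Generator,
    reversal_prob: float = 0.1,
) -> np.ndarray:
    """Split into k clusters (k uniform in 2..N), reverse each cluster with
    the given probability, then swap two randomly chosen clusters."""
    chrom = np.asarray(chrom, dtype=int)
    n = chrom.shape[0]
    if n < 2:
        raise ValueError("cluster shuffling needs at least 2 genes")
    k = int(rng.integers(2, n + 1))
    cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
    clusters = [list(c) for c in np.split(chrom, cuts)]
    for c in clusters:
        if rng.random() < reversal_prob:
            c.reverse()
    a, b = rng.choice(k, size=2, replace=False)
    clusters[a], clusters[b] = clusters[b], clusters[a]
    return np.concatenate([np.array(c, dtype=int) for c in clusters])


def swap_mutation(
    chrom: Sequence[int], mutation_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene Bernoulli trigger; a triggered gene swaps with a uniformly
    chosen position (possibly itself).  The gene multiset is preserved."""
    out = np.array(chrom, dtype=int)
    n = out.shape[0]
    if mutation_rate <= 0.0:
        return out
    for k in range(n):
        if rng.random() < mutation_rate:
            other = int(rng.integers(0, n))
            out[k], out[other] = out[other], out[k]
    return out


def evolve(
    cfg: GAConfig,
    population_fitness: PopulationFitness,
    n_sites: int,
) -> GAResult:
    """Run the GA and return the best ordering with a per-generation log.

    ``population_fitness`` scores a whole (M, N) ordering matrix at once
    (see :mod:`spinorder.fitness` for the two shipped variants).  History
    columns: generation, best, mean (over valid chromosomes), n_valid.
    Stops early when ``cfg.target_score`` is reached.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg.n_pop, n_sites, rng)
    scores, valid = population_fitness(pop)
    hist: list[tuple[int, float, float, int]] = []
    best_idx = int(np.argmax(scores))
    best = pop[best_idx].copy()
    best_score = float(scores[best_idx])
    reached = False

    def log(gen: int) -> None:
        vs = scores[valid]
        hist.append((gen, best_score, float(vs.mean()) if vs.size else float("nan"), int(valid.sum())))

    log(0)
    gen = 0
    for gen in range(1, cfg.generations + 1):
        if cfg.target_score is not None and best_score >= cfg.target_score - 1e-12:
            gen -= 1
            reached = True
            break
        elite = elite_selection(pop, scores, cfg.n_elite)
        weights = selection_weights(scores, valid)
        pool = select_mating_pool(pop, weights, cfg.n_pop - cfg.n_elite, rng)
        pairing = rng.permutation(pool.shape[0])
        cs_gen = cfg.cs_period is not None and gen % cfg.cs_period == 0
        children = np.empty_like(pool)
        if cs_gen:
            for r, idx in enumerate(pairing):
                children[r] = cluster_shuffle(pool[idx], rng, cfg.cluster_reversal_prob)
        else:
            for r in range(0, pool.shape[0], 2):
                c1, c2 = order_crossover(pool[pairing[r]], pool[pairing[r + 1]], rng)
                children[r], children[r + 1] = c1, c2
        if cfg.mutation_rate > 0.0:
            for r in range(children.shape[0]):
                children[r] = swap_mutation(children[r], cfg.mutation_rate, rng)
        pop = np.vstack([elite, children])
        scores, valid = population_fitness(pop)
        cand = int(np.argmax(scores))
        if scores[cand] > best_score:
            best_score = float(scores[cand])
            best = pop[cand].copy()
        log(gen)
    else:
        if cfg.target_score is not None and best_score >= cfg.target_score - 1e-12:
            reached = True

    history = pd.DataFrame(hist, columns=["generation", "best", "mean", "n_valid"])
    return GAResult(
        best_ordering=tuple(int(x) for x in best),
        best_score=best_score,
        history=history,
        generations_run=gen,
        reached_target=reached,
    )
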