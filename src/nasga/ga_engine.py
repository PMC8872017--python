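"""Genetic-algorithm search over recurrent-cell genotypes.

Per generation: the top elite fraction is copied unchanged; remaining
slots are filled by capped roulette-wheel selection of parent pairs,
per-property single-point crossover (applied with the crossover rate,
otherwise cloning) and single-gene mutation.  The wheel is compressed so
that the largest area is at most ``roulette_cap`` times the smallest,
keeping low-fitness chromosomes selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cellspace import (
    ACTIVATIONS,
    Chromosome,
    init_weight,
    random_chromosome,
    weight_gene_keys,
)
from .childmodel import (
    FitnessRecord,
    SharedWeightStore,
    TrainConfig,
    commit_weights,
    materialize_model,
    train_child,
)


@dataclass
class GaConfig:
    population_size: int = 100
    elite_fraction: float = 0.10
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1  # absent from the method description; config-exposed
    roulette_cap: float = 3.0
    max_generations: int = 50
    plateau_patience: int = 10
    n_nodes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must lie in (0, 1)")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.roulette_cap <= 1.0:
            raise ValueError("roulette_cap must be > 1")


@dataclass
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    min_fitness: float
    selection_entropy: float
    store_version: int


@dataclass
class Population:
    generation: int
    chromosomes: list[Chromosome]
    best: Chromosome | None = None

    @property
    def size(self) -> int:
        return len(self.chromosomes)


def init_population(
    config: GaConfig,
    n: int,
    rng: np.random.Generator,
    n_features: int = 40,
    hidden: int = 16,
    with_weights: bool = True,
) -> Population:
    chromosomes = []
    for i in range(config.population_size):
        c = random_chromosome(n, rng, n_features=n_features, hidden=hidden, with_weights=with_weights)
        c.id = i
        chromosomes.append(c)
    return Population(generation=0, chromosomes=chromosomes)


def rescale_fitness(fitnesses: np.ndarray, cap: float = 3.0) -> np.ndarray:
    """Roulette areas: compress so max/min <= cap, preserving order.

    The shift ``b`` solving ``max + b = cap * (min + b)`` is applied when the
    raw ratio exceeds the cap (or the minimum is zero); otherwise the
    fitnesses are used as-is.  All-zero fitness yields uniform areas.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    fmax, fmin = f.max(), f.min()
    if fmax == 0.0:
        return np.ones_like(f)
    if fmax == fmin:
        return f.copy()
    if fmin == 0.0 or fmax / fmin > cap:
        b = (fmax - cap * fmin) / (cap - 1.0)
        return f + b
    return f.copy()


def roulette_select(areas: np.ndarray, rng: np.random.Generator) -> int:
    """Index drawn with probability proportional to its wheel area."""
    areas = np.asarray(areas, dtype=np.float64)
    if np.any(areas <= 0):
        raise ValueError("areas must be strictly positive")
    probs = areas / areas.sum()
    return int(rng.choice(len(areas), p=probs))


def elite_select(population: Population, fraction: float) -> list[Chromosome]:
    """Top max(1, floor(fraction * size)) chromosomes; ties broken by lower id."""
    for c in population.chromosomes:
        if c.fitness is None:
            raise ValueError(f"chromosome {c.id} has no fitness")
    k = max(1, math.floor(fraction * population.size))
    ranked = sorted(population.chromosomes, key=lambda c: (-c.fitness, c.id))
    return [c.copy() for c in ranked[:k]]


def _single_point_swap(a: list, b: list, rng: np.random.Generator) -> tuple[list, list]:
    if len(a) < 2:
        return list(a), list(b)
    cut = int(rng.integers(1, len(a)))
    return a[:cut] + b[cut:], b[:cut] + a[cut:]


def crossover(
    parent_a: Chromosome, parent_b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Independent single-point crossover per property: activations, parent
    connections, and the flattened weight-gene sequence."""
    if parent_a.n != parent_b.n:
        raise ValueError("crossover requires equal node counts")
    acts_a, acts_b = _single_point_swap(list(parent_a.activations), list(parent_b.activations), rng)
    pars_a, pars_b = _single_point_swap(list(parent_a.parents), list(parent_b.parents), rng)
    keys = weight_gene_keys(parent_a.n)
    have_weights = parent_a.weights and parent_b.weights
    if have_weights:
        wa = [parent_a.weights[k] for k in keys]
        wb = [parent_b.weights[k] for k in keys]
        wa, wb = _single_point_swap(wa, wb, rng)
        weights_a = {k: v.copy() for k, v in zip(keys, wa)}
        weights_b = {k: v.copy() for k, v in zip(keys, wb)}
    else:
        weights_a, weights_b = {}, {}
    child_a = Chromosome(parent_a.n, tuple(acts_a), tuple(int(p) for p in pars_a), weights_a)
    child_b = Chromosome(parent_b.n, tuple(acts_b), tuple(int(p) for p in pars_b), weights_b)
    return child_a, child_b


def mutate(
    chromosome: Chromosome,
    mutation_rate: float,
    rng: np.random.Generator,
    n_features: int = 40,
    hidden: int = 16,
) -> Chromosome:
    """With probability ``mutation_rate``, change exactly one gene, picked
    uniformly across activations, parent connections and weight genes."""
    if rng.random() >= mutation_rate:
        return chromosome
    out = chromosome.copy()
    n = out.n
    wkeys = weight_gene_keys(n) if out.weights else []
    total = n + (n - 1) + len(wkeys)
    g = int(rng.integers(0, total))
    if g < n:
        alternatives = [a for a in ACTIVATIONS if a != out.activations[g]]
        acts = list(out.activations)
        acts[g] = alternatives[int(rng.integers(0, len(alternatives)))]
        out.activations = tuple(acts)
    elif g < n + (n - 1):
        i = g - n  # parent gene of node i+2, domain {1..i+1}
        if i > 0:
            choices = [p for p in range(1, i + 2) if p != out.parents[i]]
            pars = list(out.parents)
            pars[i] = choices[int(rng.integers(0, len(choices)))]
            out.parents = tuple(pars)
    else:
        key = wkeys[g - n - (n - 1)]
        out.weights[key] = init_weight(key, n_features, hidden, rng)
    out.fitness = None
    return out


def next_generation(
    population: Population,
    config: GaConfig,
    rng: np.random.Generator,
    n_features: int = 40,
    hidden: int = 16,
) -> Population:
    """Elites copied; remaining slots filled by selection, crossover, mutation."""
    elites = elite_select(population, config.elite_fraction)
    areas = rescale_fitness(
        np.array([c.fitness for c in population.chromosomes]), config.roulette_cap
    )
    children: list[Chromosome] = []
    while len(elites) + len(children) < population.size:
        ia = roulette_select(areas, rng)
        ib = roulette_select(areas, rng)
        pa = population.chromosomes[ia]
        pb = population.chromosomes[ib]
        if rng.random() < config.crossover_rate:
            ca, cb = crossover(pa, pb, rng)
        else:
            ca, cb = pa.copy(), pb.copy()
            ca.fitness = None
            cb.fitness = None
        for child in (ca, cb):
            if len(elites) + len(children) >= population.size:
                break
            children.append(mutate(child, config.mutation_rate, rng, n_features, hidden))
    chromosomes = elites + children
    for i, c in enumerate(chromosomes):
        c.id = i
    return Population(
        generation=population.generation + 1, chromosomes=chromosomes, best=population.best
    )


def _selection_entropy(areas: np.ndarray) -> float:
    p = areas / areas.sum()
    return float(-np.sum(p * np.log(np.clip(p, 1e-300, None))))


def evolve(
    fitness_fn,
    config: GaConfig,
    rng: np.random.Generator,
    n_features: int = 40,
    hidden: int = 16,
    with_weights: bool = True,
    store_version_fn=None,
) -> tuple[Chromosome, list[GenerationStats]]:
    """Generic GA loop over an arbitrary fitness function.

    ``fitness_fn(chromosome, generation) -> float in [0, 1]`` is called once
    per unevaluated chromosome.  Stops on fitness plateau
    (``plateau_patience`` generations without best-so-far improvement) or at
    ``max_generations``.
    """
    population = init_population(
        config, config.n_nodes, rng, n_features=n_features, hidden=hidden, with_weights=with_weights
    )
    best: Chromosome | None = None
    stats_log: list[GenerationStats] = []
    stall = 0
    for _gen in range(config.max_generations):
        for c in population.chromosomes:
            if c.fitness is None:
                c.fitness = float(fitness_fn(c, population.generation))
        fitnesses = np.array([c.fitness for c in population.chromosomes])
        gen_best = population.chromosomes[int(np.argmax(fitnesses))]
        if best is None or gen_best.fitness > best.fitness:
            best = gen_best.copy()
            stall = 0
        else:
            stall += 1
        population.best = best
        areas = rescale_fitness(fitnesses, config.roulette_cap)
        stats_log.append(
            GenerationStats(
                generation=population.generation,
                best_fitness=float(fitnesses.max()),
                mean_fitness=float(fitnesses.mean()),
                min_fitness=float(fitnesses.min()),
                selection_entropy=_selection_entropy(areas),
                store_version=store_version_fn() if store_version_fn else 0,
            )
        )
        if stall >= config.plateau_patience:
            break
        if population.generation + 1 >= config.max_generations:
            break
        population = next_generation(population, config, rng, n_features, hidden)
    return best, stats_log


def run_search(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: GaConfig,
    train_config: TrainConfig,
    store: SharedWeightStore | None = None,
) -> tuple[Chromosome, list[GenerationStats], SharedWeightStore]:
    """Full search: fitness is validation accuracy of the trained child;
    learned weights are shared through ``store`` across all children."""
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("empty split")
    if store is None:
        store = SharedWeightStore()
    rng = np.random.default_rng(config.seed)
    n_features = train_x.shape[2]

    def fitness_fn(chromosome: Chromosome, generation: int) -> float:
        cfg = replace(train_config, seed=train_config.seed + 1000 * generation + chromosome.id)
        model = materialize_model(chromosome, store, cfg, n_features=n_features)
        record = train_child(model, train_x, train_y, val_x, val_y, cfg)
        commit_weights(model, chromosome, store)
        return record.accuracy

    best, stats = evolve(
        fitness_fn,
        config,
        rng,
        n_features=n_features,
        hidden=train_config.hidden,
        store_version_fn=lambda: store.version,
    )
    return best, stats, store
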