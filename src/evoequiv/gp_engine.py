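"""Genetic programming of wall-following robot controllers.

A population of random boolean programs (over the 8 sensors, the 4 move
indicators, ``True``/``False`` and the primitives IF/AND/OR/NOT) is
rated by mean wall coverage over journeys from random starting cells,
bred by fitness-proportionate ("wheel of fortune") selection with
subtree crossover and subtree-replacement mutation, and evolved until a
program is *perfect*: from every free start it reaches the wall and
then covers every wall cell within the journey budget.

Internal nodes are drawn with a bias toward the syntactic elements
IF/AND/OR/NOT over terminals during random program generation; the run
is fully reproducible from its seed.  Fitness evaluation freezes the
random starting cells for the whole run (variance reduction) and
memoizes on the program's compiled move policy — two programs with the
same 256-entry move table necessarily score alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import logic_expr
from .logic_expr import BoolExpr, VARIABLES
from .gridworld import (GridWorld, default_budget, move_table_for_program)

__all__ = [
    "GPConfig",
    "RatedProgram",
    "random_program",
    "rate_fitness",
    "roulette_select",
    "crossover",
    "mutate",
    "evolve",
]

_INTERNAL_KINDS = ("if", "and", "or", "not")
_TERMINALS = tuple(VARIABLES) + (True, False)


@dataclass
class GPConfig:
    """Run parameters for the wall-following GP experiment.

    ``bias_weights`` gives the relative draw weight of each internal
    primitive during random generation; ``terminal_weight`` is the total
    weight of drawing a leaf instead while depth remains.
    """

    population_size: int = 200
    generations: int = 500
    crossover_prob: float = 0.9
    mutation_prob: float = 0.4
    bias_weights: dict = field(default_factory=lambda: {
        "if": 4.0, "and": 4.0, "or": 4.0, "not": 2.0})
    terminal_weight: float = 6.0
    max_depth: int = 5
    max_nodes: int = 500
    journey_length: int = 150
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if set(self.bias_weights) != set(_INTERNAL_KINDS):
            raise ValueError("bias_weights must cover if/and/or/not")
        if min(self.bias_weights.values()) <= 0 or self.terminal_weight <= 0:
            raise ValueError("draw weights must be positive")


@dataclass(frozen=True)
class RatedProgram:
    """A program with its mean-coverage fitness and perfection flag."""

    program: BoolExpr
    fitness: float
    perfect: bool = False


def random_program(config: GPConfig, rng: np.random.Generator,
                   max_depth: int | None = None) -> BoolExpr:
    """Grow a random tree within the depth bound.

    At depth 0 a leaf is forced; above it, the node kind is drawn with
    the configured bias toward internal primitives, and leaves are drawn
    uniformly from the 12 variables plus the two constants.
    """
    if max_depth is None:
        max_depth = config.max_depth
    kinds = list(_INTERNAL_KINDS)
    weights = np.array([config.bias_weights[k] for k in kinds]
                       + [config.terminal_weight])
    probs = weights / weights.sum()

    def grow(depth: int) -> BoolExpr:
        if depth <= 0:
            choice = int(rng.integers(len(_TERMINALS)))
        else:
            pick = int(rng.choice(len(kinds) + 1, p=probs))
            if pick < len(kinds):
                kind = kinds[pick]
                arity = {"not": 1, "and": 2, "or": 2, "if": 3}[kind]
                children = tuple(grow(depth - 1) for _ in range(arity))
                return BoolExpr(kind, children)
            choice = int(rng.integers(len(_TERMINALS)))
        leaf = _TERMINALS[choice]
        if isinstance(leaf, bool):
            return logic_expr.const(leaf)
        return logic_expr.var(leaf)

    return grow(max_depth)


class _FitnessEvaluator:
    """Frozen-start coverage fitness with move-policy memoization."""

    def __init__(self, world: GridWorld, config: GPConfig,
                 starts: np.ndarray | None = None,
                 rng: np.random.Generator | None = None):
        self.world = world
        self.config = config
        self.cache = world.cache()
        if starts is None:
            if rng is None:
                raise ValueError("either starts or rng is required")
            starts = rng.choice(len(self.cache.free), size=config.n_starts,
                                replace=True)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.budget = default_budget(world)
        self.wall_total = world.n_wall_cells
        self._memo: dict[bytes, tuple[float, bool]] = {}

    def rate(self, program: BoolExpr) -> RatedProgram:
        table = move_table_for_program(program)
        key = table.tobytes()
        hit = self._memo.get(key)
        if hit is None:
            cov = self.cache.coverage(table, self.starts,
                                      self.config.journey_length)
            fitness = float(cov.mean())
            perfect = False
            if cov.min() == self.wall_total:
                # candidate: full coverage on every evaluation start
                all_cov = self.cache.coverage_all_starts(table, self.budget)
                perfect = bool((all_cov == self.wall_total).all())
            hit = (fitness, perfect)
            self._memo[key] = hit
        return RatedProgram(program, hit[0], hit[1])


def rate_fitness(program: BoolExpr, world: GridWorld, config: GPConfig,
                 rng: np.random.Generator) -> RatedProgram:
    """Mean distinct-wall-cell coverage over random starting cells.

    Each journey has the configured fixed length; the starts are drawn
    uniformly from the free cells.  The perfection flag is set only
    after verification from *every* free start.
    """
    return _FitnessEvaluator(world, config, rng=rng).rate(program)


def roulette_select(population: list[RatedProgram],
                    rng: np.random.Generator) -> RatedProgram:
    """Wheel-of-fortune draw: probability proportional to fitness.

    Falls back to a uniform draw when every fitness is zero."""
    if not population:
        raise ValueError("empty population")
    w = np.array([max(p.fitness, 0.0) for p in population])
    total = w.sum()
    if total <= 0:
        return population[int(rng.integers(len(population)))]
    return population[int(rng.choice(len(population), p=w / total))]


def crossover(p1: BoolExpr, p2: BoolExpr,
              rng: np.random.Generator) -> tuple[BoolExpr, BoolExpr]:
    """Exchange a uniformly chosen subtree of each parent."""
    i = int(rng.integers(p1.size))
    j = int(rng.integers(p2.size))
    s1 = p1.node_at(i)
    s2 = p2.node_at(j)
    return p1.replace_at(i, s2), p2.replace_at(j, s1)


def mutate(program: BoolExpr, config: GPConfig,
           rng: np.random.Generator) -> BoolExpr:
    """With the configured probability, regrow a uniformly chosen subtree."""
    if rng.random() >= config.mutation_prob:
        return program
    i = int(rng.integers(program.size))
    depth = max(1, config.max_depth - 2)
    return program.replace_at(i, random_program(config, rng, depth))


def evolve(config: GPConfig, world: GridWorld,
           rng: np.random.Generator | None = None
           ) -> tuple[RatedProgram, list[dict]]:
    """Run the generational GP loop on one world.

    Terminates at the first verified-perfect program or at the
    generation cap; the best member is copied unchanged each generation
    (elitism), so the best-fitness history is non-decreasing.  Returns
    the champion (the perfect program if one was found, otherwise the
    best-fitness program seen) and the per-generation history.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    evaluator = _FitnessEvaluator(world, config, rng=rng)
    pop = [random_program(config, rng) for _ in range(config.population_size)]
    history: list[dict] = []
    best: RatedProgram | None = None

    for gen in range(config.generations + 1):
        rated = [evaluator.rate(p) for p in pop]
        rated.sort(key=lambda r: r.fitness, reverse=True)
        if best is None or rated[0].fitness > best.fitness:
            best = rated[0]
        history.append({
            "generation": gen,
            "best_fitness": rated[0].fitness,
            "mean_fitness": float(np.mean([r.fitness for r in rated])),
            "best_size": rated[0].program.size,
        })
        perfect = next((r for r in rated if r.perfect), None)
        if perfect is not None:
            return perfect, history
        if gen == config.generations:
            break
        next_pop = [rated[0].program]  # elitism
        while len(next_pop) < config.population_size:
            m1 = roulette_select(rated, rng).program
            m2 = roulette_select(rated, rng).program
            if rng.random() < config.crossover_prob:
                c1, c2 = crossover(m1, m2, rng)
            else:
                c1, c2 = m1, m2
            for child in (c1, c2):
                if len(next_pop) >= config.population_size:
                    break
                child = mutate(child, config, rng)
                if child.size > config.max_nodes:
                    child = m1 if child is c1 else m2
                next_pop.append(child)
        pop = next_pop

    return best, history
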