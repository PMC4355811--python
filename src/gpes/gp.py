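"""Genetic programming over ternary classifier-fusion trees.

Each GP individual is itself an ensemble classifier: a syntax tree whose
leaves (terminals) reference trained base decision trees and whose internal
nodes are one of three fusion operators applied to hard -1/+1 votes:

* ``Min``   — vetoes positive: outputs -1 if any child votes -1;
* ``Max``   — vetoes negative: outputs +1 if any child votes +1;
* ``Average`` — majority vote of its three children (hard output; with an
  odd arity the mean is never exactly 0).

Every internal node has exactly three children and tree depth is capped at 3
(root counts as depth 1), so an individual fuses between 3 and 9 terminal
slots through at most two operator levels. Populations are initialized with
ramped half-and-half, evolved by subtree crossover, point mutation and
tournament selection with single elitism, and scored by validation accuracy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OPERATORS",
    "GPNode",
    "GPIndividual",
    "GPConfig",
    "evaluate_node",
    "evaluate_matrix",
    "predict_individual",
    "ramped_half_and_half_init",
    "crossover",
    "mutate",
    "evolve",
]

OPERATORS = ("Average", "Min", "Max")
ARITY = 3
MAX_DEPTH = 3


@dataclass
class GPNode:
    """A node of the fusion tree: operator node or terminal reference.

    Terminals carry ``terminal`` (an index into the base-classifier pool) and
    no children; operator nodes carry ``operator`` and exactly three children.
    """

    operator: str | None = None
    terminal: int | None = None
    children: list["GPNode"] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return self.operator is None

    def validate(self) -> None:
        if self.is_terminal:
            if self.terminal is None or self.children:
                raise ValueError("terminal node needs a classifier reference and no children")
        else:
            if self.operator not in OPERATORS:
                raise ValueError(f"unknown operator {self.operator!r}")
            if len(self.children) != ARITY:
                raise ValueError("operator nodes must have exactly 3 children")
            for child in self.children:
                child.validate()

    def depth(self) -> int:
        if self.is_terminal:
            return 1
        return 1 + max(child.depth() for child in self.children)

    def terminals(self) -> list[int]:
        if self.is_terminal:
            return [self.terminal]
        out: list[int] = []
        for child in self.children:
            out.extend(child.terminals())
        return out

    def operators(self) -> list[str]:
        if self.is_terminal:
            return []
        out = [self.operator]
        for child in self.children:
            out.extend(child.operators())
        return out


@dataclass
class GPIndividual:
    """A depth-limited ternary fusion tree with an optional cached fitness."""

    root: GPNode
    fitness: float | None = None

    def validate(self) -> None:
        if self.root.is_terminal:
            raise ValueError("the root must be an operator node")
        self.root.validate()
        if self.root.depth() > MAX_DEPTH:
            raise ValueError(f"individual exceeds the depth cap of {MAX_DEPTH}")

    def copy(self) -> "GPIndividual":
        return GPIndividual(root=copy.deepcopy(self.root), fitness=self.fitness)


@dataclass
class GPConfig:
    """Evolution hyperparameters.

    Defaults follow the reference setting: population 80, 200 generations,
    crossover probability 0.8 per selected pair, mutation probability 0.4 per
    offspring (one node changed), initial depths ramped over {2, 3}.
    """

    population_size: int = 80
    n_generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.4
    min_init_depth: int = 2
    max_init_depth: int = 3
    tournament_size: int = 2
    n_elite: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population must hold at least 2 individuals")
        if not 2 <= self.min_init_depth <= self.max_init_depth <= MAX_DEPTH:
            raise ValueError("init depth range must satisfy 2 <= min <= max <= 3")


# ---------------------------------------------------------------------------
# evaluation


def evaluate_node(node: GPNode, votes: np.ndarray) -> int:
    """Evaluate the tree for a single sample's pool votes (-1/+1 per classifier)."""
    return int(evaluate_matrix(node, np.asarray(votes).reshape(1, -1))[0])


def evaluate_matrix(node: GPNode, vote_matrix: np.ndarray) -> np.ndarray:
    """Vectorised evaluation: one -1/+1 output per row of ``vote_matrix``.

    ``vote_matrix`` holds the cached votes of every pool classifier
    (columns) on every sample (rows); terminals index into its columns. On
    signed unit votes, Min/Max are the elementwise min/max of the child
    outputs and Average is the sign of their sum (odd arity, never zero).
    """
    if node.is_terminal:
        if node.terminal is None or node.terminal >= vote_matrix.shape[1]:
            raise IndexError(f"unresolved classifier reference {node.terminal!r}")
        return vote_matrix[:, node.terminal].astype(int)
    child_out = np.stack([evaluate_matrix(c, vote_matrix) for c in node.children])
    if node.operator == "Min":
        return child_out.min(axis=0)
    if node.operator == "Max":
        return child_out.max(axis=0)
    return np.where(child_out.sum(axis=0) < 0, -1, 1)


def predict_individual(ind: GPIndividual, vote_matrix: np.ndarray) -> np.ndarray:
    """Per-sample -1/+1 prediction of an individual from pool votes."""
    return evaluate_matrix(ind.root, vote_matrix)


# ---------------------------------------------------------------------------
# initialization


def _grow(depth_left: int, pool_size: int, rng: np.random.Generator, full: bool) -> GPNode:
    """Build a subtree with at most ``depth_left`` levels below (inclusive)."""
    if depth_left == 1:
        return GPNode(terminal=int(rng.integers(pool_size)))
    if not full and rng.random() < 0.5:
        # grow-method nodes may stop early, producing unbalanced trees
        return GPNode(terminal=int(rng.integers(pool_size)))
    return GPNode(
        operator=OPERATORS[rng.integers(len(OPERATORS))],
        children=[_grow(depth_left - 1, pool_size, rng, full) for _ in range(ARITY)],
    )


def _make_individual(
    depth: int, pool_size: int, rng: np.random.Generator, full: bool
) -> GPIndividual:
    root = GPNode(
        operator=OPERATORS[rng.integers(len(OPERATORS))],
        children=[_grow(depth - 1, pool_size, rng, full) for _ in range(ARITY)],
    )
    ind = GPIndividual(root=root)
    ind.validate()
    return ind


def ramped_half_and_half_init(
    cfg: GPConfig, pool_size: int, rng: np.random.Generator
) -> list[GPIndividual]:
    """Ramped half-and-half initial population.

    The population is divided evenly over target depths in
    [min_init_depth, max_init_depth]; at each depth half the trees are
    "full" (every level below the root is an operator until the target depth)
    and half are "grow" (non-root nodes may stop early at a terminal),
    yielding a mix of balanced and heavily unbalanced trees. Remainders from
    the even division are assigned round-robin.
    """
    if pool_size < 1:
        raise ValueError("terminal pool is empty")
    depths = list(range(cfg.min_init_depth, cfg.max_init_depth + 1))
    cells = [(d, full) for d in depths for full in (True, False)]
    population: list[GPIndividual] = []
    for i in range(cfg.population_size):
        depth, full = cells[i % len(cells)]
        population.append(_make_individual(depth, pool_size, rng, full))
    return population


# ---------------------------------------------------------------------------
# variation


def _paths(node: GPNode, prefix: tuple[int, ...] = ()) -> list[tuple[int, ...]]:
    """All node paths (tuples of child positions); () is the root."""
    out = [prefix]
    for i, child in enumerate(node.children):
        out.extend(_paths(child, prefix + (i,)))
    return out


def _get(node: GPNode, path: tuple[int, ...]) -> GPNode:
    for i in path:
        node = node.children[i]
    return node


def _set(root: GPNode, path: tuple[int, ...], sub: GPNode) -> None:
    parent = _get(root, path[:-1])
    parent.children[path[-1]] = sub


def crossover(
    a: GPIndividual,
    b: GPIndividual,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> tuple[GPIndividual, GPIndividual]:
    """Swap a uniformly chosen non-root subtree between two parents.

    Offspring that would exceed the depth cap trigger a re-draw of both
    crossover points (up to ``max_retries``); if no legal pair is found the
    parents are returned as copies. Arity and root invariants always hold.
    """
    for _ in range(max_retries):
        ca, cb = a.copy(), b.copy()
        paths_a = [p for p in _paths(ca.root) if p]
        paths_b = [p for p in _paths(cb.root) if p]
        pa = paths_a[rng.integers(len(paths_a))]
        pb = paths_b[rng.integers(len(paths_b))]
        sub_a = _get(ca.root, pa)
        sub_b = _get(cb.root, pb)
        _set(ca.root, pa, sub_b)
        _set(cb.root, pb, sub_a)
        if ca.root.depth() <= MAX_DEPTH and cb.root.depth() <= MAX_DEPTH:
            ca.fitness = cb.fitness = None
            return ca, cb
    return a.copy(), b.copy()


def mutate(
    ind: GPIndividual, pool_size: int, rng: np.random.Generator
) -> GPIndividual:
    """Point mutation: replace one uniformly chosen node in place.

    A terminal is redirected to a random pool classifier; an operator node is
    switched to a different operator. The tree structure never changes, so
    all invariants are preserved by construction.
    """
    out = ind.copy()
    paths = _paths(out.root)
    node = _get(out.root, paths[rng.integers(len(paths))])
    if node.is_terminal:
        node.terminal = int(rng.integers(pool_size))
    else:
        choices = [op for op in OPERATORS if op != node.operator]
        node.operator = choices[rng.integers(len(choices))]
    out.fitness = None
    return out


# ---------------------------------------------------------------------------
# evolution loop


def _fitness(
    ind: GPIndividual,
    vote_matrix: np.ndarray,
    y: np.ndarray,
    fitness_groups: list[np.ndarray] | None,
) -> float:
    pred = predict_individual(ind, vote_matrix)
    if fitness_groups is None:
        return float(np.mean(pred == y))
    return float(np.mean([np.mean(pred[g] == y[g]) for g in fitness_groups]))


def _tournament(
    population: list[GPIndividual], size: int, rng: np.random.Generator
) -> GPIndividual:
    picks = rng.integers(len(population), size=size)
    best = max(picks, key=lambda i: (population[i].fitness, -i))
    return population[best]


def evolve(
    cfg: GPConfig,
    pool_size: int,
    vote_matrix: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    fitness_groups: list[np.ndarray] | None = None,
    history: list[dict] | None = None,
) -> list[GPIndividual]:
    """Run the generational loop and return the final population.

    Fitness is an individual's accuracy on the validation fold, computed from
    the cached vote matrix (``fitness_groups``, if given, switches to the
    mean of per-group accuracies for the cross-validated fitness mode).
    Each generation keeps ``n_elite`` best individuals, then fills the
    population with tournament-selected parents recombined with probability
    ``crossover_rate`` and point-mutated with probability ``mutation_rate``.
    With elitism the best fitness is non-decreasing across generations.
    If ``history`` is supplied, per-generation best/mean fitness is appended.
    """
    if pool_size < 1 or vote_matrix.shape[1] < pool_size:
        raise ValueError("vote matrix must cover the terminal pool")
    population = ramped_half_and_half_init(cfg, pool_size, rng)
    for ind in population:
        ind.fitness = _fitness(ind, vote_matrix, y, fitness_groups)
    for gen in range(cfg.n_generations):
        ranked = sorted(
            range(len(population)), key=lambda i: (-population[i].fitness, i)
        )
        next_pop = [population[i].copy() for i in ranked[: cfg.n_elite]]
        while len(next_pop) < cfg.population_size:
            pa = _tournament(population, cfg.tournament_size, rng)
            pb = _tournament(population, cfg.tournament_size, rng)
            if rng.random() < cfg.crossover_rate:
                ca, cb = crossover(pa, pb, rng)
            else:
                ca, cb = pa.copy(), pb.copy()
            for child in (ca, cb):
                if len(next_pop) >= cfg.population_size:
                    break
                if rng.random() < cfg.mutation_rate:
                    child = mutate(child, pool_size, rng)
                next_pop.append(child)
        population = next_pop
        for ind in population:
            if ind.fitness is None:
                ind.fitness = _fitness(ind, vote_matrix, y, fitness_groups)
        if history is not None:
            fits = [ind.fitness for ind in population]
            history.append(
                {"generation": gen + 1, "best": max(fits), "mean": float(np.mean(fits))}
            )
    return population
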