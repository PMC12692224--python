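"""Genetic-algorithm maximization over the composition simplex.

The strain-ratio optimization is a box-free problem on the simplex
{x >= 0, sum(x) = 1}: the equality constraint is handled structurally,
not by penalty.  Initialization samples uniformly from the simplex
(flat Dirichlet), blend crossover is a convex combination (closed under
the simplex), and Gaussian mutation is followed by Euclidean projection
back onto the simplex.  Elitism makes the best-fitness history
monotone; a brute-force lattice search is provided as an independent
oracle for verifying GA optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mixture_design import Composition, validate_composition

__all__ = [
    "GAConfig",
    "GAResult",
    "FitnessEvaluationError",
    "ga_maximize",
    "grid_maximize",
    "project_to_simplex",
]

Fitness = Callable[[np.ndarray], float]

#: improvement smaller than this does not reset the stall counter
STALL_EPS = 1e-10


class FitnessEvaluationError(RuntimeError):
    """Fitness returned a non-finite value; carries the offending point."""

    def __init__(self, x: np.ndarray, value: float):
        self.composition = np.asarray(x)
        super().__init__(
            f"fitness returned non-finite value {value!r} at composition {list(x)}"
        )


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    max_generations: int = 200
    crossover_rate: float = 0.8
    mutation_sd: float = 0.05
    elite_count: int = 2
    stall_generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be non-negative")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be < population_size")
        if self.max_generations < 1 or self.stall_generations < 1:
            raise ValueError("generation counts must be positive")


@dataclass(frozen=True)
class GAResult:
    best: Composition
    best_fitness: float
    history: tuple[float, ...]
    generations_run: int
    seed: int


def project_to_simplex(x: np.ndarray) -> np.ndarray:
    """Euclidean projection of an arbitrary real vector onto the simplex.

    Sort-based algorithm: find the largest k such that the top-k entries,
    shifted by a common theta to sum to 1, stay positive; clip the rest
    to zero.  Runs in O(q log q).
    """
    x = np.asarray(x, dtype=float)
    u = np.sort(x)[::-1]
    css = np.cumsum(u)
    ks = np.arange(1, len(x) + 1)
    cond = u - (css - 1.0) / ks > 0
    k = int(ks[cond][-1])
    theta = (css[k - 1] - 1.0) / k
    return np.maximum(x - theta, 0.0)


def _eval(fitness: Fitness, x: np.ndarray) -> float:
    v = float(fitness(x))
    if not np.isfinite(v):
        raise FitnessEvaluationError(x, v)
    return v


def ga_maximize(fitness: Fitness, q: int, config: GAConfig | None = None) -> GAResult:
    """Maximize ``fitness`` over the (q-1)-simplex.

    Every individual evaluated in every generation is a valid
    composition (non-negative, summing to one).  Selection is a size-2
    tournament; the run stops at ``max_generations`` or after
    ``stall_generations`` generations without improvement.  Identical
    config and seed reproduce the result exactly.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    cfg = config or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population_size

    pop = rng.dirichlet(np.ones(q), size=n)
    fit = np.array([_eval(fitness, ind) for ind in pop])

    best_x = pop[int(np.argmax(fit))].copy()
    best_f = float(fit.max())
    history = [best_f]
    stall = 0
    gen = 0

    for gen in range(1, cfg.max_generations + 1):
        order = np.argsort(fit)[::-1]
        elites = pop[order[: cfg.elite_count]].copy()

        # size-2 tournament selection for the non-elite slots
        n_children = n - cfg.elite_count
        children = np.empty((n_children, q))
        for c in range(n_children):
            i, j = rng.integers(0, n, size=2)
            a = pop[i] if fit[i] >= fit[j] else pop[j]
            if rng.random() < cfg.crossover_rate:
                i2, j2 = rng.integers(0, n, size=2)
                b = pop[i2] if fit[i2] >= fit[j2] else pop[j2]
                lam = rng.random()
                child = lam * a + (1.0 - lam) * b
            else:
                child = a.copy()
            if cfg.mutation_sd > 0:
                child = project_to_simplex(
                    child + rng.normal(0.0, cfg.mutation_sd, size=q)
                )
            children[c] = child

        pop = np.vstack([elites, children])
        fit = np.array([_eval(fitness, ind) for ind in pop])

        gen_best = float(fit.max())
        if gen_best > best_f + STALL_EPS:
            best_f = gen_best
            best_x = pop[int(np.argmax(fit))].copy()
            stall = 0
        else:
            if gen_best > best_f:
                best_f = gen_best
                best_x = pop[int(np.argmax(fit))].copy()
            stall += 1
        history.append(best_f)
        if stall >= cfg.stall_generations:
            break

    return GAResult(
        best=validate_composition(best_x),
        best_fitness=best_f,
        history=tuple(history),
        generations_run=gen,
        seed=cfg.seed,
    )


def grid_maximize(
    fitness: Fitness, q: int, step: float = 0.01
) -> tuple[Composition, float]:
    """Exhaustive search over the lattice of compositions at resolution ``step``.

    ``step`` must divide 1 (e.g. 0.01, 0.005).  Ties are broken
    lexicographically (the lattice is enumerated in lexicographic
    descending order and only strict improvements replace the incumbent).
    Guards against grids above 10^7 points.
    """
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9 or m < 1:
        raise ValueError(f"step {step!r} does not divide 1")
    from math import comb

    n_points = comb(q + m - 1, m)
    if n_points > 10**7:
        raise ValueError(
            f"grid at step {step} has {n_points} points (> 1e7); coarsen the step"
        )

    from .mixture_design import _lattice_points

    best_x: np.ndarray | None = None
    best_f = -np.inf
    for c in _lattice_points(q, m):
        x = np.array(c, dtype=float) / m
        v = _eval(fitness, x)
        if v > best_f:
            best_f = v
            best_x = x
    assert best_x is not None
    return validate_composition(best_x), float(best_f)
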