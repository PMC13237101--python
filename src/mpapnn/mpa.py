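"""Marine Predators Algorithm (MPA) over a bounded continuous box.

The optimizer mimics marine predator/prey foraging.  A population of
candidate solutions ("prey") moves through three phases as the iteration
budget is spent:

* phase 1 (first third) — exploration: Brownian prey steps around the elite;
* phase 2 (middle third) — half the population takes Lévy prey steps, the
  other half Brownian predator steps scaled by the adaptive factor CF;
* phase 3 (last third) — exploitation: Lévy predator steps around the elite.

After each phase update a FADs/eddy perturbation is applied with probability
``fads_probability`` to escape local optima.  The best solution seen so far
(the "top predator") is kept in elite memory and never worsens; each prey
index additionally remembers the best position it has ever held
("marine memory saving").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy import special

__all__ = [
    "SearchSpace",
    "MPAConfig",
    "Population",
    "EliteState",
    "ConvergenceTrace",
    "initialize_population",
    "sample_brownian",
    "sample_levy",
    "mantegna_sigma_u",
    "compute_cf",
    "phase_for_iteration",
    "phase_update",
    "fads_perturbation",
    "optimize",
]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box the optimizer searches.

    ``lower`` and ``upper`` are length-``dim`` vectors with
    ``lower[j] < upper[j]`` for every coordinate.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower: Sequence[float], upper: Sequence[float]):
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if lower.ndim != 1 or upper.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if lower.size == 0:
            raise ValueError("search space must have at least one dimension")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if not (lower < upper).all():
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        """Project positions back into the box (nearest-bound clamping)."""
        return np.clip(positions, self.lower, self.upper)

    @classmethod
    def unit(cls, dim: int) -> "SearchSpace":
        """The [0, 1]^dim box used when tuning PNN weights and biases."""
        return cls(np.zeros(dim), np.ones(dim))


@dataclass(frozen=True)
class MPAConfig:
    """MPA parameters.

    Defaults follow the benchmark configuration: population 10, 100
    iterations, step constant P=0.5, FADs probability 0.2, Lévy exponent
    β=1.5, elite memory on, no early stopping.
    """

    population_size: int = 10
    max_iterations: int = 100
    step_constant: float = 0.5
    fads_probability: float = 0.2
    levy_exponent: float = 1.5
    fads_w_convention: Literal["sparse", "paper_literal"] = "sparse"
    patience: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if not 0.0 <= self.fads_probability <= 1.0:
            raise ValueError("fads_probability must lie in [0, 1]")
        if not 0.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy_exponent must lie in (0, 2]")
        if self.fads_w_convention not in ("sparse", "paper_literal"):
            raise ValueError("unknown FADs mask convention")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be a positive integer when set")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class Population:
    """Prey matrix (N×dim) and the objective value of each row."""

    positions: np.ndarray
    fitness: np.ndarray


@dataclass
class EliteState:
    """Top-predator memory plus per-index best positions (marine memory)."""

    elite_position: np.ndarray
    elite_fitness: float
    memory_positions: np.ndarray
    memory_fitness: np.ndarray


@dataclass
class ConvergenceTrace:
    """Best objective value after each iteration (monotone under elite memory)."""

    best_fitness_per_iteration: list = field(default_factory=list)

    @property
    def iterations_executed(self) -> int:
        return len(self.best_fitness_per_iteration)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(1, self.iterations_executed + 1),
                "best_fitness": self.best_fitness_per_iteration,
            }
        ).to_csv(path, index=False)


Objective = Callable[[np.ndarray], float]


def _evaluate(objective: Objective, positions: np.ndarray) -> np.ndarray:
    values = np.empty(positions.shape[0])
    for i, row in enumerate(positions):
        v = float(objective(row))
        if not np.isfinite(v):
            raise ValueError(f"objective returned a non-finite value for individual {i}")
        values[i] = v
    return values


def initialize_population(
    space: SearchSpace,
    config: MPAConfig,
    objective: Objective,
    rng: Optional[np.random.Generator] = None,
    seed_positions: Optional[np.ndarray] = None,
) -> tuple[Population, EliteState, np.random.Generator]:
    """Draw the initial prey uniformly in the box and set up elite memory.

    ``seed_positions`` (k×dim, k ≤ N) overwrite the first k random rows; the
    hybrid trainer uses this to plant the identity encoding.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.population_size
    u = rng.uniform(size=(n, space.dim))
    positions = space.lower + u * (space.upper - space.lower)
    if seed_positions is not None:
        seed_positions = np.atleast_2d(np.asarray(seed_positions, dtype=float))
        if seed_positions.shape[0] > n or seed_positions.shape[1] != space.dim:
            raise ValueError("seed_positions must be k×dim with k <= population_size")
        positions[: seed_positions.shape[0]] = space.clamp(seed_positions)
    fitness = _evaluate(objective, positions)
    pop = Population(positions=positions, fitness=fitness)
    elite = EliteState(
        elite_position=positions[0].copy(),
        elite_fitness=float(fitness[0]),
        memory_positions=positions.copy(),
        memory_fitness=fitness.copy(),
    )
    return pop, elite, rng


def sample_brownian(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal (zero-mean, unit-variance) step matrix."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    return rng.standard_normal((rows, cols))


def mantegna_sigma_u(beta: float) -> float:
    """Scale of the numerator normal in the Mantegna Lévy-step construction."""
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must lie in (0, 2]")
    num = special.gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = special.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def sample_levy(rows: int, cols: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Lévy step matrix via the Mantegna construction.

    x = u / |v|^(1/β) with u ~ N(0, σ_u²), v ~ N(0, 1).  At β=2 the tail is
    Gaussian; below 2 it follows a power law, producing the occasional long
    jumps that drive exploration.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    sigma_u = mantegna_sigma_u(beta)
    u = rng.standard_normal((rows, cols)) * sigma_u
    v = rng.standard_normal((rows, cols))
    return u / np.abs(v) ** (1.0 / beta)


def compute_cf(t: int, t_max: int) -> float:
    """Adaptive step-size factor CF = (1 − t/t_max)^(2^(t/t_max)).

    CF(0)=1 and CF(t_max)=0; strictly decreasing in between, shrinking
    predator moves as iterations pass (CF(t_max/2) = 0.5^sqrt(2) ≈ 0.3752).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if t < 0 or t > t_max:
        raise ValueError("iteration index must lie in [0, t_max]")
    frac = t / t_max
    return float((1.0 - frac) ** (2.0**frac))


def phase_for_iteration(t: int, t_max: int) -> int:
    """Phase schedule: 1 for t < t_max/3, 2 for t < 2·t_max/3, else 3."""
    if t < 0 or t >= t_max:
        raise ValueError("iteration index must lie in [0, t_max)")
    if t < t_max / 3.0:
        return 1
    if t < 2.0 * t_max / 3.0:
        return 2
    return 3


def phase_update(
    pop: Population,
    elite: EliteState,
    t: int,
    config: MPAConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> Population:
    """One velocity-ratio phase step; returns a new clamped population.

    Random draws are consumed in a fixed, phase-dependent order so runs are
    reproducible from the generator state alone: phase 1 draws R_B (N×dim)
    then R (N×dim); phase 2 draws R_L, R for the prey half then R_B for the
    predator half; phase 3 draws R_L (N×dim).
    """
    n, dim = pop.positions.shape
    if dim != space.dim or elite.elite_position.size != dim:
        raise ValueError("population/elite dimensions inconsistent with the search space")
    phase = phase_for_iteration(t, config.max_iterations)
    p = config.step_constant
    cf = compute_cf(t, config.max_iterations)

    u = pop.positions
    el = elite.elite_position  # broadcast as the replicated elite matrix

    if phase == 1:
        r_b = sample_brownian(n, dim, rng)
        r = rng.uniform(size=(n, dim))
        step = r_b * (el - r_b * u)
        new = u + p * r * step
    elif phase == 2:
        new = u.copy()
        half = n // 2
        if half >= 1:
            # prey half: Lévy exploration
            r_l = sample_levy(half, dim, config.levy_exponent, rng)
            r = rng.uniform(size=(half, dim))
            step = r_l * (el - r_l * u[:half])
            new[:half] = u[:half] + p * r * step
        # predator half: Brownian exploitation around the elite
        r_b = sample_brownian(n - half, dim, rng)
        step = r_b * (r_b * el - u[half:])
        new[half:] = el + p * cf * step
    else:
        r_l = sample_levy(n, dim, config.levy_exponent, rng)
        step = r_l * (r_l * el - u)
        new = el + p * cf * step

    return Population(positions=space.clamp(new), fitness=pop.fitness.copy())


def fads_perturbation(
    pop: Population,
    elite: EliteState,
    t: int,
    config: MPAConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> Population:
    """Eddy-formation / fish-aggregating-device perturbation.

    Per individual, with probability ``fads_probability`` take a masked jump
    toward a random point of the box scaled by CF; otherwise drift along the
    difference of two other random prey.  With fewer than two individuals the
    drift branch is unavailable and the masked jump is always applied.
    Draw order: r5 (N), R (N×dim), mask draws (N×dim), r (N), index pairs.
    """
    n, dim = pop.positions.shape
    if dim != space.dim:
        raise ValueError("population dimension inconsistent with the search space")
    cf = compute_cf(t, config.max_iterations)
    fads = config.fads_probability

    r5 = rng.uniform(size=n)
    r_mat = rng.uniform(size=(n, dim))
    w_draw = rng.uniform(size=(n, dim))
    if config.fads_w_convention == "sparse":
        w = (w_draw < fads).astype(float)
    else:  # paper_literal: draws >= fads map to 1
        w = (w_draw >= fads).astype(float)
    r_vec = rng.uniform(size=n)
    if n >= 2:
        r1 = rng.integers(0, n, size=n)
        r2 = (r1 + 1 + rng.integers(0, n - 1, size=n)) % n
    else:
        r1 = r2 = np.zeros(n, dtype=int)

    new = pop.positions.copy()
    jump = r5 < fads
    if n < 2:
        jump = np.ones(n, dtype=bool)
    box_point = space.lower + r_mat * (space.upper - space.lower)
    new[jump] = pop.positions[jump] + cf * box_point[jump] * w[jump]
    drift = ~jump
    mult = (fads * (1.0 - r_vec) + r_vec)[:, None]
    diff = pop.positions[r1] - pop.positions[r2]
    new[drift] = pop.positions[drift] + (mult * diff)[drift]

    return Population(positions=space.clamp(new), fitness=pop.fitness.copy())


def _better(a: float, b: float, maximize: bool) -> bool:
    return a > b if maximize else a < b


def _memory_and_elite(
    pop: Population, elite: EliteState, maximize: bool
) -> tuple[Population, EliteState]:
    """Marine memory saving: per index, keep the better of new vs remembered;
    then refresh the elite."""
    if maximize:
        worse = pop.fitness < elite.memory_fitness
    else:
        worse = pop.fitness > elite.memory_fitness
    pop.positions[worse] = elite.memory_positions[worse]
    pop.fitness[worse] = elite.memory_fitness[worse]
    elite.memory_positions = pop.positions.copy()
    elite.memory_fitness = pop.fitness.copy()

    best_i = int(np.argmax(pop.fitness) if maximize else np.argmin(pop.fitness))
    if _better(float(pop.fitness[best_i]), elite.elite_fitness, maximize):
        elite.elite_fitness = float(pop.fitness[best_i])
        elite.elite_position = pop.positions[best_i].copy()
    return pop, elite


def optimize(
    objective: Objective,
    space: SearchSpace,
    config: MPAConfig,
    direction: Literal["minimize", "maximize"] = "minimize",
    seed_positions: Optional[np.ndarray] = None,
    callback: Optional[Callable[[int, EliteState], None]] = None,
) -> tuple[np.ndarray, float, ConvergenceTrace]:
    """Run the full MPA loop and return (best position, best fitness, trace).

    Each iteration applies the phase update, evaluates and saves memory,
    refreshes the elite, then applies the FADs perturbation with a second
    evaluation/memory/elite pass.  Early stopping (``config.patience``)
    terminates the loop once the elite has not improved for that many
    consecutive iterations.
    """
    if direction not in ("minimize", "maximize"):
        raise ValueError("direction must be 'minimize' or 'maximize'")
    maximize = direction == "maximize"

    pop, elite, rng = initialize_population(
        space, config, objective, seed_positions=seed_positions
    )
    # initialization evaluated the whole population once; make sure the elite
    # starts at the true initial best
    pop, elite = _memory_and_elite(pop, elite, maximize)

    trace = ConvergenceTrace()
    stall = 0
    for t in range(config.max_iterations):
        previous_best = elite.elite_fitness

        pop = phase_update(pop, elite, t, config, space, rng)
        try:
            pop.fitness = _evaluate(objective, pop.positions)
        except ValueError as err:
            raise ValueError(f"objective failed at iteration {t} (phase update): {err}") from err
        pop, elite = _memory_and_elite(pop, elite, maximize)

        pop = fads_perturbation(pop, elite, t, config, space, rng)
        try:
            pop.fitness = _evaluate(objective, pop.positions)
        except ValueError as err:
            raise ValueError(f"objective failed at iteration {t} (FADs): {err}") from err
        pop, elite = _memory_and_elite(pop, elite, maximize)

        trace.best_fitness_per_iteration.append(elite.elite_fitness)
        if callback is not None:
            callback(t, elite)

        if config.patience is not None:
            if _better(elite.elite_fitness, previous_best, maximize):
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break

    return elite.elite_position.copy(), elite.elite_fitness, trace
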