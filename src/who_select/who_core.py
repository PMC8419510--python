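"""Wildebeest Herd Optimization (WHO) as a general box-bounded continuous minimizer.

The herd metaphor decomposes each iteration into five per-candidate moves —
local "milling" probes, a leader-weighted local update, imitation of a fitter
peer (herd instinct), a random escape when a candidate worsened (starvation
avoidance), and a pull toward the global best when moderately far from it
(herd pressure) — followed by one population-level move that re-seeds the
worst candidate near the global best (social memory).

Everything is written for minimization: "fitness" is the objective value and
lower is better.  A global best-ever candidate is tracked with strict elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "BoundsSpec",
    "WHOConfig",
    "RandomSource",
    "Candidate",
    "Population",
    "MillingSet",
    "OptimizeResult",
    "BoundsError",
    "ConfigError",
    "EvaluationError",
    "PeerSelectionError",
    "initialize_population",
    "milling",
    "local_update",
    "herd_instinct",
    "starvation_avoidance",
    "herd_pressure",
    "social_memory",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


class BoundsError(ValueError):
    """Lower bound exceeds upper bound somewhere, or shapes disagree."""


class ConfigError(ValueError):
    """An optimizer configuration value violates its contract."""


class EvaluationError(RuntimeError):
    """The objective returned a non-finite value."""


class PeerSelectionError(ValueError):
    """A candidate was offered itself as its herd-instinct peer."""


@dataclass(frozen=True)
class BoundsSpec:
    """Box constraints: each coordinate j lives in [lower[j], upper[j]]."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or upper.ndim != 1 or lower.shape != upper.shape:
            raise BoundsError("lower and upper must be 1-D vectors of equal length")
        if lower.size == 0:
            raise BoundsError("bounds must have at least one dimension")
        if np.any(lower > upper):
            raise BoundsError("lower bound exceeds upper bound in some coordinate")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dimension(self) -> int:
        return int(self.lower.size)

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clamp(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def contains(self, position: np.ndarray) -> bool:
        return bool(
            np.all(position >= self.lower) and np.all(position <= self.upper)
        )

    @classmethod
    def cube(cls, lower: float, upper: float, dimension: int) -> "BoundsSpec":
        return cls(np.full(dimension, float(lower)), np.full(dimension, float(upper)))


@dataclass(frozen=True)
class WHOConfig:
    """Tuning knobs for the herd.

    ``learning_rate`` (the milling step scale) and ``crowding_threshold``
    (the herd-pressure upper distance) default to ``None`` meaning
    "derive from the bounds at optimize time": 0.1 * mean(range) and
    0.3 * ||range|| respectively.  ``pressure_lower_bound`` exposes the
    lower distance of the herd-pressure window (the rule fires only when
    pressure_lower_bound < distance-to-best < crowding_threshold, so with
    the default lower bound 1.0 it is inert whenever the threshold <= 1).
    """

    population_size: int = 30
    iterations: int = 15
    milling_steps: int = 3
    learning_rate: Optional[float] = None
    # alpha1 = 1 makes the local update a pure interpolation between the
    # best probe and the old position ((1-beta1)*z + beta1*x); values < 1
    # add a hidden contraction toward the origin that biases benchmarks
    # whose optimum sits there.
    alpha1: float = 1.0
    beta1: float = 0.3
    alpha2: float = 0.2
    beta2: float = 0.8
    crowding_threshold: Optional[float] = None
    pressure_lower_bound: float = 1.0
    social_memory_radius: float = 0.1
    use_social_memory: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.milling_steps < 1:
            raise ConfigError("milling_steps must be >= 1")
        if self.learning_rate is not None and self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.crowding_threshold is not None and self.crowding_threshold <= 0:
            raise ConfigError("crowding_threshold must be > 0")
        if self.social_memory_radius <= 0:
            raise ConfigError("social_memory_radius must be > 0")

    def resolve(self, bounds: BoundsSpec) -> "WHOConfig":
        """Fill bounds-dependent defaults, returning a fully concrete config."""
        lr = self.learning_rate
        if lr is None:
            lr = 0.1 * float(np.mean(bounds.range))
        eta = self.crowding_threshold
        if eta is None:
            eta = 0.3 * float(np.linalg.norm(bounds.range))
            if eta <= 0.0:  # degenerate bounds: keep the invariant eta > 0
                eta = 1e-12
        return replace(self, learning_rate=lr, crowding_threshold=eta)


class RandomSource:
    """Seeded draw stream used by every stochastic operator.

    Two primitives: ``theta()`` is uniform on [0, 1); ``unit_vector(d)`` is
    an isotropic random direction with Euclidean norm exactly 1 (Gaussian
    draw, normalized; a degenerate near-zero draw is redrawn).  All of the
    differently-decorated unit vectors in the herd equations are modelled
    as independent draws from this single primitive.
    """

    def __init__(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def theta(self) -> float:
        return float(self._rng.random())

    def uniform(self, low: np.ndarray, high: np.ndarray) -> np.ndarray:
        return self._rng.uniform(low, high)

    def integer(self, n: int) -> int:
        return int(self._rng.integers(n))

    def unit_vector(self, dimension: int) -> np.ndarray:
        while True:
            v = self._rng.standard_normal(dimension)
            norm = np.linalg.norm(v)
            if norm > 1e-30:
                return v / norm


@dataclass
class Candidate:
    """A herd member: a position and (once evaluated) its objective value."""

    position: np.ndarray
    fitness: Optional[float] = None

    def copy(self) -> "Candidate":
        return Candidate(self.position.copy(), self.fitness)


@dataclass
class MillingSet:
    probes: list  # positions, clamped to bounds
    probe_fitness: list
    best_probe: np.ndarray
    best_fitness: float


@dataclass
class Population:
    candidates: list
    best: Optional[Candidate] = None
    iteration: int = 0


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list
    evaluations: int

    def to_dict(self) -> dict:
        return {
            "best_position": [float(x) for x in self.best_position],
            "best_fitness": float(self.best_fitness),
            "trace": [float(x) for x in self.trace],
            "evaluations": int(self.evaluations),
        }


def _evaluate(objective: Objective, position: np.ndarray) -> float:
    value = float(objective(position))
    if not np.isfinite(value):
        raise EvaluationError(
            f"objective returned non-finite value {value!r} at position "
            f"{np.asarray(position).tolist()}"
        )
    return value


def initialize_population(
    bounds: BoundsSpec, config: WHOConfig, rng: RandomSource
) -> Population:
    """Draw ``population_size`` positions uniformly inside the box."""
    candidates = [
        Candidate(rng.uniform(bounds.lower, bounds.upper))
        for _ in range(config.population_size)
    ]
    return Population(candidates=candidates, best=None, iteration=0)


def milling(
    candidate: Candidate,
    objective: Objective,
    bounds: BoundsSpec,
    config: WHOConfig,
    rng: RandomSource,
) -> MillingSet:
    """Probe ``milling_steps`` small random steps around the candidate.

    Each probe is position + learning_rate * theta * unit_vector with fresh
    draws, clamped into the box; the best probe (lowest objective) is kept.
    """
    cfg = config.resolve(bounds)
    probes = []
    values = []
    for _ in range(cfg.milling_steps):
        theta = rng.theta()
        nu = rng.unit_vector(bounds.dimension)
        probe = bounds.clamp(candidate.position + cfg.learning_rate * theta * nu)
        probes.append(probe)
        values.append(_evaluate(objective, probe))
    best_idx = int(np.argmin(values))
    return MillingSet(
        probes=probes,
        probe_fitness=values,
        best_probe=probes[best_idx],
        best_fitness=values[best_idx],
    )


def local_update(
    candidate: Candidate,
    milling_set: MillingSet,
    objective: Objective,
    bounds: BoundsSpec,
    config: WHOConfig,
) -> Candidate:
    """Blend the candidate with its best probe:
    new = alpha1 * best_probe + beta1 * (position - best_probe), clamped."""
    z = milling_set.best_probe
    new_pos = bounds.clamp(config.alpha1 * z + config.beta1 * (candidate.position - z))
    return Candidate(new_pos, _evaluate(objective, new_pos))


def herd_instinct(
    candidate: Candidate,
    peer: Candidate,
    objective: Objective,
    bounds: BoundsSpec,
    config: WHOConfig,
) -> Candidate:
    """Move toward a strictly fitter peer: new = alpha2*x + beta2*x_peer.

    If the peer is not strictly fitter the candidate is returned unchanged
    (no wasted evaluation).
    """
    if peer is candidate:
        raise PeerSelectionError("peer must be a different candidate object")
    if peer.fitness is None or candidate.fitness is None:
        raise ConfigError("herd_instinct requires evaluated candidate and peer")
    if not peer.fitness < candidate.fitness:
        return candidate
    new_pos = bounds.clamp(config.alpha2 * candidate.position + config.beta2 * peer.position)
    return Candidate(new_pos, _evaluate(objective, new_pos))


def starvation_avoidance(
    candidate: Candidate,
    fitness_before: float,
    objective: Objective,
    bounds: BoundsSpec,
    rng: RandomSource,
) -> Candidate:
    """Random range-scaled escape, applied only if the candidate worsened
    this iteration (fitness rose above ``fitness_before``)."""
    if candidate.fitness is None:
        raise ConfigError("starvation_avoidance requires an evaluated candidate")
    if not candidate.fitness > fitness_before:
        return candidate
    theta = rng.theta()
    vbar = rng.unit_vector(bounds.dimension)
    new_pos = bounds.clamp(candidate.position + theta * bounds.range * vbar)
    return Candidate(new_pos, _evaluate(objective, new_pos))


def herd_pressure(
    candidate: Candidate,
    best: Candidate,
    objective: Objective,
    bounds: BoundsSpec,
    config: WHOConfig,
    rng: RandomSource,
) -> Candidate:
    """Snap a moderately-distant candidate next to the global best.

    Fires only when pressure_lower_bound < ||best - x|| < crowding_threshold
    (Euclidean); the compound window is taken literally, so it is inert when
    crowding_threshold <= pressure_lower_bound.
    """
    cfg = config.resolve(bounds)
    distance = float(np.linalg.norm(best.position - candidate.position))
    if not (cfg.pressure_lower_bound < distance < cfg.crowding_threshold):
        return candidate
    n_hat = rng.unit_vector(bounds.dimension)
    new_pos = bounds.clamp(best.position + cfg.learning_rate * n_hat)
    return Candidate(new_pos, _evaluate(objective, new_pos))


def social_memory(
    population: Population,
    objective: Objective,
    bounds: BoundsSpec,
    config: WHOConfig,
    rng: RandomSource,
) -> Population:
    """Replace the worst candidate with a point within
    ``social_memory_radius`` of the global best (clamped)."""
    if population.best is None or population.best.fitness is None:
        raise ConfigError("social_memory requires an evaluated global best")
    values = [c.fitness for c in population.candidates]
    if any(v is None for v in values):
        raise ConfigError("social_memory requires a fully evaluated population")
    worst_idx = int(np.argmax(values))  # ties: argmax keeps the lowest index
    nu_hat = rng.unit_vector(bounds.dimension)
    new_pos = bounds.clamp(
        population.best.position + config.social_memory_radius * nu_hat
    )
    new_cand = Candidate(new_pos, _evaluate(objective, new_pos))
    population.candidates[worst_idx] = new_cand
    if new_cand.fitness < population.best.fitness:
        population.best = new_cand.copy()
    return population


def optimize(
    objective: Objective,
    bounds: BoundsSpec,
    config: Optional[WHOConfig] = None,
    rng: Optional[RandomSource] = None,
) -> OptimizeResult:
    """Run the full herd loop and return the best-ever solution.

    Per iteration, each candidate goes through milling -> local update ->
    herd instinct -> starvation avoidance -> herd pressure; then the social
    memory move runs once.  The returned trace records the best-ever fitness
    after every iteration and is nonincreasing by elitism.
    """
    if config is None:
        config = WHOConfig()
    cfg = config.resolve(bounds)
    if rng is None:
        rng = RandomSource(cfg.seed)

    eval_count = 0

    def tracked(position: np.ndarray) -> float:
        nonlocal eval_count
        eval_count += 1
        return _evaluate(objective, position)

    population = initialize_population(bounds, cfg, rng)
    for cand in population.candidates:
        cand.fitness = tracked(cand.position)
    best_idx = int(np.argmin([c.fitness for c in population.candidates]))
    population.best = population.candidates[best_idx].copy()

    def consider(cand: Candidate) -> None:
        if cand.fitness < population.best.fitness:
            population.best = cand.copy()

    trace = []
    for iteration in range(cfg.iterations):
        population.iteration = iteration + 1
        for i, cand in enumerate(population.candidates):
            fitness_before = cand.fitness

            mset = milling(cand, tracked, bounds, cfg, rng)
            cand = local_update(cand, mset, tracked, bounds, cfg)
            consider(cand)

            peer_idx = rng.integer(len(population.candidates) - 1)
            if peer_idx >= i:
                peer_idx += 1
            cand = herd_instinct(
                cand, population.candidates[peer_idx], tracked, bounds, cfg
            )
            consider(cand)

            cand = starvation_avoidance(cand, fitness_before, tracked, bounds, rng)
            consider(cand)

            cand = herd_pressure(cand, population.best, tracked, bounds, cfg, rng)
            consider(cand)

            population.candidates[i] = cand
        if cfg.use_social_memory:
            social_memory(population, tracked, bounds, cfg, rng)
        trace.append(population.best.fitness)

    return OptimizeResult(
        best_position=population.best.position.copy(),
        best_fitness=population.best.fitness,
        trace=trace,
        evaluations=eval_count,
    )
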