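"""Synthetic labeled feature matrices and continuous benchmark objectives.

The generator emulates the statistics of a high-redundancy deep-feature
vector: a few class-informative Gaussian features, correlated redundant
copies of them, and pure-noise features, with columns shuffled and the
ground-truth informative indices returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["SyntheticSpec", "BenchmarkObjective", "generate", "benchmark"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 300
    n_informative: int = 5
    n_redundant: int = 10
    n_noise: int = 35
    effect_size: float = 1.5
    redundancy_rho: float = 0.8
    class_balance: float = 0.5
    rectify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("n_redundant and n_noise must be >= 0")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if not 0 < self.redundancy_rho < 1:
            raise ValueError("redundancy_rho must be in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass(frozen=True)
class BenchmarkObjective:
    name: str
    dimension: int
    objective: Callable[[np.ndarray], float]
    known_optimum_value: float
    known_optimum_position: np.ndarray
    default_lower: float
    default_upper: float

    def __call__(self, x: np.ndarray) -> float:
        return self.objective(x)


def generate(spec: SyntheticSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (matrix, labels, informative_indices) deterministically per seed.

    Labels are Bernoulli(class_balance) for the positive class, forced to
    contain both classes.  Informative columns are unit-variance normals
    with class means +-effect_size/2; each redundant column correlates
    rho with a randomly chosen informative column; noise columns are
    independent standard normals.  Columns are shuffled; the returned
    index vector locates the informative columns in the shuffled matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = (rng.random(n) < spec.class_balance).astype(int)
    if labels.sum() == 0:
        labels[0] = 1
    elif labels.sum() == n:
        labels[0] = 0

    shift = np.where(labels == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
    informative = rng.standard_normal((n, spec.n_informative)) + shift[:, None]

    rho = spec.redundancy_rho
    redundant = np.empty((n, spec.n_redundant))
    for j in range(spec.n_redundant):
        src = rng.integers(spec.n_informative)
        redundant[:, j] = rho * informative[:, src] + np.sqrt(
            1.0 - rho**2
        ) * rng.standard_normal(n)

    noise = rng.standard_normal((n, spec.n_noise))

    matrix = np.concatenate([informative, redundant, noise], axis=1)
    perm = rng.permutation(spec.n_features)
    matrix = matrix[:, perm]
    # perm maps new column -> old column; informative old columns are 0..k-1
    informative_idx = np.sort(np.flatnonzero(perm < spec.n_informative))

    if spec.rectify:
        matrix = np.maximum(matrix, 0.0)
    return matrix, labels, informative_idx


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def _quadratic1d(x: np.ndarray) -> float:
    return float((np.asarray(x)[0] - 2.0) ** 2)


def benchmark(name: str, dimension: int = 1) -> BenchmarkObjective:
    """Named benchmark objective with its analytic optimum and a sensible
    default box."""
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    if name == "sphere":
        return BenchmarkObjective(
            name, dimension, _sphere, 0.0, np.zeros(dimension), -5.0, 5.0
        )
    if name == "rastrigin":
        return BenchmarkObjective(
            name, dimension, _rastrigin, 0.0, np.zeros(dimension), -5.12, 5.12
        )
    if name == "quadratic1d":
        if dimension != 1:
            raise ValueError("quadratic1d is one-dimensional")
        return BenchmarkObjective(
            name, 1, _quadratic1d, 0.0, np.array([2.0]), 0.0, 5.0
        )
    raise ValueError(f"unknown benchmark {name!r}")
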